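"""Permutation-based ligand-receptor interaction testing between cell types.

For every ordered cell-type pair (A, B) and ligand-receptor gene pair, the
interaction score is the product of the ligand's mean normalized expression
in A and the receptor's in B, considered only when both genes are detected
in at least 10% of the respective type's cells. Significance comes from a
cluster-label permutation null: labels of all cells are shuffled jointly
(one shuffle per round, reused for every candidate), scores recomputed, and

    p = (1 + #{permuted score >= observed}) / (n_perm + 1).

A second, marker-based screen requires the ligand to be a strong marker of
the sender type (p-value-derived Z > 4) and the receptor at least weakly
enriched in the receiver (Z > 0); reported interactions pass both screens.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig

logger = logging.getLogger("nichecompare")


def _cluster_means(expr: np.ndarray, onehot: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Mean expression per cluster: (genes x cells) @ (cells x k) / sizes."""
    return (expr @ onehot) / sizes[None, :]


def lr_score(
    norm_expr: np.ndarray,
    genes: Sequence[str],
    clusters: Sequence,
    lr_table: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Score candidate interactions passing the expression-ratio gate.

    Returns one row per (ligand, receptor, cell_type_a, cell_type_b) whose
    ligand is expressed (normalized value > 0) in >= ``lr_expr_ratio`` of
    A's cells and receptor in >= that fraction of B's cells. Clusters with
    fewer than ``lr_min_cells`` cells are skipped. LR pairs with either gene
    absent from the matrix are skipped with a warning.
    """
    config = config or AnalysisConfig()
    clusters = np.asarray(clusters).astype(str)
    labels = sorted(pd.unique(clusters))
    sizes = np.array([(clusters == lab).sum() for lab in labels])
    keep = sizes >= config.lr_min_cells
    dropped = [lab for lab, k in zip(labels, keep) if not k]
    if dropped:
        logger.warning("clusters with <%d cells skipped: %s", config.lr_min_cells, dropped)
    labels = [lab for lab, k in zip(labels, keep) if k]
    sizes = sizes[keep]

    gi = {g: i for i, g in enumerate(genes)}
    norm_expr = np.asarray(norm_expr, dtype=float)
    onehot = np.stack([(clusters == lab).astype(float) for lab in labels], axis=1)
    means = _cluster_means(norm_expr, onehot, sizes)
    ratios = _cluster_means((norm_expr > 0).astype(float), onehot, sizes)

    rows = []
    for _, pair in lr_table.iterrows():
        lig, rec = pair["ligand"], pair["receptor"]
        if lig not in gi or rec not in gi:
            logger.warning("LR pair (%s, %s): gene absent from matrix; skipped", lig, rec)
            continue
        li, ri = gi[lig], gi[rec]
        for a_idx, a in enumerate(labels):
            if ratios[li, a_idx] < config.lr_expr_ratio:
                continue
            for b_idx, b in enumerate(labels):
                if ratios[ri, b_idx] < config.lr_expr_ratio:
                    continue
                rows.append(
                    {
                        "ligand": lig,
                        "receptor": rec,
                        "cell_type_a": a,
                        "cell_type_b": b,
                        "expr_ratio_ligand": ratios[li, a_idx],
                        "expr_ratio_receptor": ratios[ri, b_idx],
                        "mean_ligand_a": means[li, a_idx],
                        "mean_receptor_b": means[ri, b_idx],
                        "score": means[li, a_idx] * means[ri, b_idx],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "cell_type_a", "cell_type_b",
            "expr_ratio_ligand", "expr_ratio_receptor",
            "mean_ligand_a", "mean_receptor_b", "score",
        ],
    )


def lr_permutation_test(
    norm_expr: np.ndarray,
    genes: Sequence[str],
    clusters: Sequence,
    candidates: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Label-permutation p-values for scored candidates.

    One joint shuffle of all cell labels per round, reused across candidates
    (valid under exchangeability and matches common practice). Add-one
    p-values keep p >= 1/(n_perm + 1).
    """
    config = config or AnalysisConfig()
    if config.lr_n_perm < 100:
        logger.warning("lr_n_perm=%d < 100: unstable p-value floor", config.lr_n_perm)
    out = candidates.copy()
    if out.empty:
        out["p"] = np.array([], dtype=float)
        out["passes_perm"] = np.array([], dtype=bool)
        return out
    clusters = np.asarray(clusters).astype(str)
    labels = sorted(pd.unique(clusters))
    sizes = np.array([(clusters == lab).sum() for lab in labels])
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    gi = {g: i for i, g in enumerate(genes)}

    used_genes = sorted({*out["ligand"], *out["receptor"]})
    grows = np.array([gi[g] for g in used_genes])
    sub = np.asarray(norm_expr, dtype=float)[grows]
    ug = {g: i for i, g in enumerate(used_genes)}

    lig_r = np.array([ug[g] for g in out["ligand"]])
    rec_r = np.array([ug[g] for g in out["receptor"]])
    a_c = np.array([lab_idx[c] for c in out["cell_type_a"]])
    b_c = np.array([lab_idx[c] for c in out["cell_type_b"]])
    observed = out["score"].to_numpy()

    rng = np.random.default_rng(config.seed)
    onehot = np.stack([(clusters == lab).astype(float) for lab in labels], axis=1)
    exceed = np.zeros(len(out))
    for _ in range(config.lr_n_perm):
        perm = rng.permutation(onehot.shape[0])
        means = _cluster_means(sub, onehot[perm], sizes)
        perm_score = means[lig_r, a_c] * means[rec_r, b_c]
        exceed += perm_score >= observed
    out["p"] = (1.0 + exceed) / (config.lr_n_perm + 1.0)
    out["passes_perm"] = out["p"] <= config.lr_p
    return out


def lr_z_screen(
    lr_result: pd.DataFrame,
    marker_table: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Marker-Z screen: ligand Z > 4 in the sender, receptor Z > 0 in the receiver.

    ``marker_table`` is the output of
    :func:`nichecompare.markers.find_markers` on the same clustering. Missing
    (gene, cluster) marker entries are treated as Z = 0 (failing both strict
    screens) and logged. Adds ``ligand_z, receptor_z, passes_z, reported``;
    reported interactions require the permutation and Z screens jointly.
    """
    config = config or AnalysisConfig()
    zmap = marker_table.set_index(["gene", "cluster"])["z"]

    def lookup(gene, cluster):
        try:
            return float(zmap.loc[(gene, cluster)])
        except KeyError:
            logger.warning("no marker entry for (%s, %s); Z treated as 0", gene, cluster)
            return 0.0

    out = lr_result.copy()
    out["ligand_z"] = [
        lookup(g, c) for g, c in zip(out["ligand"], out["cell_type_a"])
    ]
    out["receptor_z"] = [
        lookup(g, c) for g, c in zip(out["receptor"], out["cell_type_b"])
    ]
    out["passes_z"] = (out["ligand_z"] > config.lr_ligand_z) & (
        out["receptor_z"] > config.lr_receptor_z
    )
    out["reported"] = out["passes_perm"] & out["passes_z"]
    return out


def interaction_counts(lr_result: pd.DataFrame) -> pd.DataFrame:
    """Reported-interaction counts per (sender, receiver) cell-type pair."""
    rep = lr_result[lr_result["reported"]]
    return (
        rep.groupby(["cell_type_a", "cell_type_b"])
        .size()
        .rename("n_interactions")
        .reset_index()
    )
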