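"""Marker detection and gene-set signature scoring.

Markers are found per cluster with a one-vs-rest two-sided Wilcoxon rank-sum
test; the ranking statistic is the signed probit transform of the p-value,

    z = sign(mean_in - mean_out) * Phi^{-1}(1 - p/2),

capped at |z| <= 37 to avoid infinities from underflowing p-values. A gene
passes the marker filter when z strictly exceeds the configured threshold
(default 3).

Signature scores are the unweighted mean of normalized expression over the
signature genes present in the matrix, per cell; sample-level scores are the
arithmetic mean over a sample's (optionally cell-type-restricted) cells, and
condition contrasts are sample-level Wilcoxon rank-sum tests with
Benjamini-Hochberg correction across the pairs tested in one call.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AnalysisConfig, GeneSignature, drop_missing_genes

logger = logging.getLogger("nichecompare")

Z_CAP = 37.0


def p_to_z(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed probit transform of two-sided p-values, capped at |z| <= 37."""
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(p / 2.0)
    z = np.minimum(z, Z_CAP)
    return np.sign(sign) * z


def _ranksum_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p-values (asymptotic, tie-corrected).

    Degenerate rows where every pooled value is identical get p = 1.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            x, y, axis=-1, alternative="two-sided", method="asymptotic"
        )
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    constant = (np.ptp(x, axis=-1) == 0) & (np.ptp(y, axis=-1) == 0) & (
        x[..., 0] == y[..., 0]
    )
    p[np.isnan(p) | constant] = 1.0
    return p


def find_markers(
    norm_expr: np.ndarray,
    genes: Sequence[str],
    clusters: Sequence,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """One-vs-rest marker test for every (cluster, gene).

    Parameters
    ----------
    norm_expr
        Normalized expression, genes x cells.
    genes
        Gene symbols for the rows of ``norm_expr``.
    clusters
        Per-cell cluster labels. Clusters with fewer than 3 cells are skipped
        with a warning.

    Returns a DataFrame with columns ``gene, cluster, mean_in, mean_out, p,
    padj, z, passes``; BH correction is applied across genes within each
    cluster, and ``passes`` reflects ``z > config.marker_z``.
    """
    config = config or AnalysisConfig()
    clusters = np.asarray(clusters)
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    norm_expr = np.asarray(norm_expr, dtype=float)
    out = []
    for lab in sorted(map(str, labels)):
        mask = clusters.astype(str) == lab
        if mask.sum() < 3:
            logger.warning("cluster %s has <3 cells; skipped", lab)
            continue
        x, y = norm_expr[:, mask], norm_expr[:, ~mask]
        mean_in, mean_out = x.mean(axis=1), y.mean(axis=1)
        p = _ranksum_rows(x, y)
        z = p_to_z(p, mean_in - mean_out)
        padj = multipletests(p, method="fdr_bh")[1]
        out.append(
            pd.DataFrame(
                {
                    "gene": list(genes),
                    "cluster": lab,
                    "mean_in": mean_in,
                    "mean_out": mean_out,
                    "p": p,
                    "padj": padj,
                    "z": z,
                    "passes": z > config.marker_z,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def score_signature(
    norm_expr: np.ndarray, genes: Sequence[str], signature: GeneSignature
) -> np.ndarray:
    """Per-cell signature score: mean normalized expression of present genes.

    Signature genes absent from the matrix are dropped with a warning; an
    error is raised when none remain.
    """
    present = drop_missing_genes(signature.genes, genes, f"signature {signature.name}")
    if not present:
        raise ValueError(
            f"no genes of signature {signature.name!r} present in matrix "
            f"(missing: {signature.genes})"
        )
    gi = {g: i for i, g in enumerate(genes)}
    rows = [gi[g] for g in present]
    return np.asarray(norm_expr, dtype=float)[rows, :].mean(axis=0)


def sample_scores(
    cell_scores: np.ndarray,
    cell_meta: pd.DataFrame,
    cell_type: str | None = None,
) -> pd.Series:
    """Per-sample mean of cell scores, optionally within one cell type."""
    df = cell_meta[["sample_id", "cluster"]].copy()
    df["score"] = np.asarray(cell_scores, dtype=float)
    if cell_type is not None:
        df = df[df["cluster"] == cell_type]
    return df.groupby("sample_id")["score"].mean()


def compare_signature_across_conditions(
    cell_scores: np.ndarray,
    cell_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
    condition_pairs: Sequence[tuple[str, str]],
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Sample-level Wilcoxon contrasts of a signature between conditions.

    Each compared condition must contribute >=2 samples with >=1 qualifying
    cell; pairs failing this are reported with ``tested = False``. BH is
    applied across the pairs tested in this call.
    """
    scores = sample_scores(cell_scores, cell_meta, cell_type)
    cond = sample_meta.set_index("sample_id")["condition"]
    rows = []
    for a, b in condition_pairs:
        sa = scores[scores.index.map(cond) == a].to_numpy()
        sb = scores[scores.index.map(cond) == b].to_numpy()
        row = {
            "condition_a": a,
            "condition_b": b,
            "n_a": len(sa),
            "n_b": len(sb),
            "median_a": float(np.median(sa)) if len(sa) else np.nan,
            "median_b": float(np.median(sb)) if len(sb) else np.nan,
        }
        if len(sa) < 2 or len(sb) < 2:
            logger.warning("pair (%s, %s) skipped: <2 qualifying samples", a, b)
            row.update({"p": np.nan, "tested": False})
        else:
            row.update({"p": float(_ranksum_rows(sa, sb)[0]), "tested": True})
        rows.append(row)
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    tested = out["tested"].fillna(False).to_numpy(dtype=bool)
    if tested.any():
        out.loc[tested, "padj"] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out
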