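"""Proportion-weighted expression distances between samples, and MDS.

For each (sample, subpopulation) with enough cells, a pseudobulk profile is
formed by summing raw counts, library-size normalizing to 10,000, and taking
log1p. The distance between two samples is the weighted sum of per-shared-
subpopulation Pearson correlation distances (1 - r), with weights
proportional to the mean of the two samples' subpopulation proportions,
renormalized over the subpopulations present in both samples. Distances are
projected to 2D with classical (Torgerson) metric MDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, CountMatrix

logger = logging.getLogger("nichecompare")


@dataclass
class PseudobulkProfiles:
    """Normalized pseudobulk profiles keyed by (sample_id, subpopulation)."""

    profiles: dict[tuple[str, str], np.ndarray]
    cell_counts: dict[tuple[str, str], int]
    sample_totals: dict[str, int]  # total cells per sample (pre-gating)
    genes: list[str]


def pseudobulk_profiles(
    counts: CountMatrix,
    cell_meta: pd.DataFrame,
    min_cells: int = 10,
) -> PseudobulkProfiles:
    """Sum counts per (sample, subpopulation), normalize, log1p.

    Pairs with fewer than ``min_cells`` cells are dropped. Profiles are
    invariant to cell order.
    """
    meta = cell_meta.set_index("barcode").loc[counts.cells]
    keys = list(zip(meta["sample_id"], meta["cluster"]))
    profiles: dict[tuple[str, str], np.ndarray] = {}
    cell_counts: dict[tuple[str, str], int] = {}
    df = pd.DataFrame({"key": keys, "col": np.arange(counts.n_cells)})
    for key, grp in df.groupby("key", sort=True):
        cols = grp["col"].to_numpy()
        if len(cols) < min_cells:
            continue
        summed = np.asarray(counts.counts[:, cols].sum(axis=1)).ravel().astype(float)
        total = summed.sum()
        profiles[key] = np.log1p(summed / total * 1e4 if total > 0 else summed)
        cell_counts[key] = len(cols)
    sample_totals = meta.groupby("sample_id").size().to_dict()
    return PseudobulkProfiles(profiles, cell_counts, sample_totals, list(counts.genes))


@dataclass
class ExpressionDistance:
    samples: list[str]
    D: np.ndarray  # symmetric, zero diagonal; NaN where undefined
    weights: pd.DataFrame  # long: sample_a, sample_b, subpopulation, weight, d_sub


def expression_distance(
    pb: PseudobulkProfiles, config: AnalysisConfig | None = None
) -> ExpressionDistance:
    """Pairwise proportion-weighted correlation distances between samples.

    Profiles are restricted to the most variable genes across pseudobulks
    (``config.n_top_genes_distance``, default 2000) before computing Pearson
    correlations. Pairs sharing no subpopulation get a NaN distance and a
    warning; they are excluded from MDS.
    """
    config = config or AnalysisConfig()
    samples = sorted({s for s, _ in pb.profiles})
    if len(samples) < 2:
        raise ValueError("need >=2 samples with pseudobulk profiles")
    mat = np.stack(list(pb.profiles.values()))
    var = mat.var(axis=0)
    k = min(config.n_top_genes_distance, mat.shape[1])
    top = np.sort(np.argsort(var, kind="stable")[::-1][:k])

    # subpopulation proportions within each sample (over all its cells)
    props: dict[tuple[str, str], float] = {
        (s, sub): pb.cell_counts[(s, sub)] / pb.sample_totals[s]
        for (s, sub) in pb.profiles
    }
    n = len(samples)
    D = np.full((n, n), np.nan)
    np.fill_diagonal(D, 0.0)
    rows = []
    subs_by_sample = {
        s: {sub for (ss, sub) in pb.profiles if ss == s} for s in samples
    }
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = samples[i], samples[j]
            shared = sorted(subs_by_sample[si] & subs_by_sample[sj])
            if not shared:
                logger.warning("samples %s and %s share no subpopulation", si, sj)
                continue
            w = np.array([(props[(si, s)] + props[(sj, s)]) / 2 for s in shared])
            w = w / w.sum()
            d = 0.0
            for s, ws in zip(shared, w):
                pi = pb.profiles[(si, s)][top]
                pj = pb.profiles[(sj, s)][top]
                if pi.std() == 0 or pj.std() == 0:
                    r = 0.0  # constant profile: no linear association
                else:
                    r = float(np.corrcoef(pi, pj)[0, 1])
                d_sub = 1.0 - r
                d += ws * d_sub
                rows.append(
                    {
                        "sample_a": si,
                        "sample_b": sj,
                        "subpopulation": s,
                        "weight": ws,
                        "d_sub": d_sub,
                    }
                )
            D[i, j] = D[j, i] = d
    return ExpressionDistance(samples, D, pd.DataFrame(rows))


def mds_project(dist: ExpressionDistance) -> pd.DataFrame:
    """Classical (Torgerson) MDS to 2D.

    Exact for Euclidean-embeddable distance matrices; output is centered at
    the origin and deterministic up to sign/rotation, so downstream
    comparisons should use embedded pairwise distances, not raw coordinates.
    Samples with any undefined (NaN) distance are excluded with a warning.
    """
    D = dist.D
    if not np.allclose(np.nan_to_num(D), np.nan_to_num(D.T)):
        raise ValueError("distance matrix must be symmetric")
    keep = ~np.isnan(D).any(axis=1)
    if not keep.all():
        dropped = [s for s, k in zip(dist.samples, keep) if not k]
        logger.warning("samples with undefined distances excluded from MDS: %s", dropped)
    Dk = D[np.ix_(keep, keep)]
    n = Dk.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dk**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)[np.newaxis, :]
    return pd.DataFrame(
        {
            "sample_id": [s for s, k in zip(dist.samples, keep) if k],
            "mds_1": coords[:, 0],
            "mds_2": coords[:, 1],
        }
    )
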