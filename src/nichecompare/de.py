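"""Pseudobulk differential expression between sample groups for one cell type.

The workflow follows the pseudobulk paradigm: counts of a cell type are
aggregated per sample, samples contributing fewer than ``de_min_cells``
(default 10) cells are excluded and samples exceeding ``de_max_cells``
(default 320) are downsampled to that many cells (uniformly, seeded), and
the aggregated counts are tested with a negative-binomial Wald test:

* size factors by DESeq-style median-of-ratios (library-size ratios when
  fewer than 10 genes are positive in every sample);
* gene-wise dispersion by method-of-moments on normalized counts, pooled
  within groups and floored at 1e-8 (variance model mu + alpha * mu^2);
* per-group NB means fitted by Newton iteration on the score equation with
  size-factor offsets; Wald z = log2FC / SE from the Fisher information.

No dispersion or fold-change shrinkage is applied; calibration is checked by
simulation instead. A leave-one-out resampling wrapper removes one random
sample per round, re-runs aggregation and testing, and summarizes per-gene
medians plus the fraction of rounds each gene stayed significant.

Significance uses ``padj < 0.05`` and ``|log2FC| > 1.5`` by default. An
independent-filtering analogue excludes genes with mean normalized count
below ``de_min_mean_norm`` from the BH family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AnalysisConfig, CountMatrix
from .markers import p_to_z  # noqa: F401  (shared z convention)

logger = logging.getLogger("nichecompare")

LN2 = np.log(2.0)


@dataclass
class DEDesign:
    """Record of the aggregation actually used for one comparison."""

    cell_type: str
    samples_a: list[str]
    samples_b: list[str]
    cells_per_sample: dict[str, int]  # after gating/downsampling
    n_resamplings: int
    seed: int


def aggregate_pseudobulk(
    counts: CountMatrix,
    cell_meta: pd.DataFrame,
    cell_type: str,
    samples_a: list[str],
    samples_b: list[str],
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, DEDesign]:
    """Aggregate raw counts of one cell type per sample, with cell gating.

    Samples with < ``de_min_cells`` cells of the type are excluded; samples
    with more than ``de_max_cells`` are downsampled (without replacement,
    seeded). Returns genes x samples arrays for the two groups plus the
    design record. Raises when either group retains fewer than 2 samples.
    """
    config = config or AnalysisConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    meta = cell_meta.set_index("barcode").loc[counts.cells].reset_index()
    mask_type = (meta["cluster"] == cell_type).to_numpy()
    if not mask_type.any():
        raise ValueError(f"cell type {cell_type!r} not present")

    def build(sample_list):
        cols, kept, ncells = [], [], {}
        for sid in sample_list:
            idx = np.flatnonzero(mask_type & (meta["sample_id"] == sid).to_numpy())
            if len(idx) < config.de_min_cells:
                logger.warning(
                    "sample %s: %d cells of %s < %d; excluded",
                    sid, len(idx), cell_type, config.de_min_cells,
                )
                continue
            if len(idx) > config.de_max_cells:
                idx = np.sort(rng.choice(idx, size=config.de_max_cells, replace=False))
            cols.append(
                np.asarray(counts.counts[:, idx].sum(axis=1)).ravel()
            )
            kept.append(sid)
            ncells[sid] = len(idx)
        return cols, kept, ncells

    cols_a, kept_a, nc_a = build(samples_a)
    cols_b, kept_b, nc_b = build(samples_b)
    if len(kept_a) < 2 or len(kept_b) < 2:
        raise ValueError(
            f"fewer than 2 samples per group after gating "
            f"({len(kept_a)} vs {len(kept_b)})"
        )
    design = DEDesign(cell_type, kept_a, kept_b, {**nc_a, **nc_b},
                      config.de_n_resamplings, seed)
    return np.column_stack(cols_a), np.column_stack(cols_b), design


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios; library-size fallback for sparse designs."""
    positive = (counts > 0).all(axis=1)
    if positive.sum() >= 10:
        logg = np.log(counts[positive])
        ref = logg.mean(axis=1)
        sf = np.exp(np.median(logg - ref[:, None], axis=0))
    else:
        lib = counts.sum(axis=0).astype(float)
        sf = lib / stats.gmean(lib[lib > 0])
    return sf / stats.gmean(sf)


def _fit_group(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray):
    """Per-gene NB mean for one group with size-factor offsets.

    Solves the score equation sum_i (y_i - s_i q) / (1 + alpha s_i q) = 0 in
    b = log q by Newton iteration, vectorized over genes. Returns (b, info)
    where info is the Fisher information sum_i mu_i / (1 + alpha mu_i).
    """
    mean0 = (y / sf[None, :]).mean(axis=1)
    zero = mean0 <= 0
    b = np.log(np.where(zero, 1.0, mean0))
    for _ in range(30):
        mu = sf[None, :] * np.exp(b)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        fisher = (mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
        step = np.where(fisher > 0, score / np.maximum(fisher, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = sf[None, :] * np.exp(b)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    b[zero] = -np.inf
    info[zero] = 0.0
    return b, info


def _mom_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Pooled method-of-moments NB dispersion alpha, floored at 1e-8."""
    alphas = []
    for m in (norm_a, norm_b):
        mu = m.mean(axis=1)
        var = m.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu**2
        alphas.append(np.where(np.isfinite(a), a, 0.0))
    alpha = np.mean(alphas, axis=0)
    return np.maximum(alpha, 1e-8)


def nb_wald_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    genes: list[str] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test, group A vs group B (log2FC = A relative to B).

    Returns per gene: base_mean (mean normalized count), log2fc, se, p, padj
    and ``tested`` (False for all-zero genes and genes excluded by the
    mean-count filter; those are left out of the BH family).
    """
    config = config or AnalysisConfig()
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    for m in (counts_a, counts_b):
        if not np.allclose(m, np.round(m)):
            raise ValueError("nb_wald_test requires raw integer counts")
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >=2 samples per group")
    n_genes = counts_a.shape[0]
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]

    both = np.column_stack([counts_a, counts_b]).astype(float)
    sf = _size_factors(both)
    sf_a, sf_b = sf[: counts_a.shape[1]], sf[counts_a.shape[1] :]
    norm_a = counts_a / sf_a[None, :]
    norm_b = counts_b / sf_b[None, :]
    base_mean = np.column_stack([norm_a, norm_b]).mean(axis=1)
    alpha = _mom_dispersion(norm_a, norm_b)

    b_a, info_a = _fit_group(counts_a.astype(float), sf_a, alpha)
    b_b, info_b = _fit_group(counts_b.astype(float), sf_b, alpha)

    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = (b_a - b_b) / LN2
        se = np.sqrt(
            np.where(info_a > 0, 1.0 / np.maximum(info_a, 1e-300), np.inf)
            + np.where(info_b > 0, 1.0 / np.maximum(info_b, 1e-300), np.inf)
        ) / LN2
        wald = np.where(np.isfinite(log2fc) & np.isfinite(se), log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))

    all_zero = (counts_a.sum(axis=1) + counts_b.sum(axis=1)) == 0
    # one group all-zero: report a large finite effect with p from the
    # conservative zero-information Wald (z = 0 -> p = 1)
    one_zero = (~all_zero) & (~np.isfinite(log2fc))
    with np.errstate(invalid="ignore"):
        zero_dir = np.where(np.isneginf(b_b), 1.0, -1.0)
    log2fc = np.where(one_zero, zero_dir * 30.0, log2fc)
    log2fc = np.where(np.isnan(log2fc), 0.0, log2fc)
    p = np.where(one_zero, 1.0, p)

    tested = (~all_zero) & (base_mean >= config.de_min_mean_norm)
    padj = np.full(n_genes, np.nan)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    p = np.where(all_zero, np.nan, p)
    return pd.DataFrame(
        {
            "gene": genes,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "tested": tested,
        }
    )


def loo_resampled_de(
    counts: CountMatrix,
    cell_meta: pd.DataFrame,
    cell_type: str,
    samples_a: list[str],
    samples_b: list[str],
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, DEDesign]:
    """Leave-one-out resampled DE: remove one random sample per round.

    Runs ``config.de_n_resamplings`` rounds (default 100); each removes one
    uniformly chosen sample from the pooled design, re-aggregates and
    re-tests. Per gene the final p and log2FC are medians across rounds,
    ``support`` is the fraction of rounds significant at the configured
    thresholds (BH within round), and ``padj`` is BH applied to the median
    p-values. Rounds violating the >=2-samples-per-group precondition are
    skipped; fewer than half successful rounds is an error.
    """
    config = config or AnalysisConfig()
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError("LOO resampling needs >=3 samples per group")
    ss = np.random.SeedSequence(config.seed)
    round_seeds = ss.generate_state(config.de_n_resamplings)
    all_samples = list(samples_a) + list(samples_b)
    rng = np.random.default_rng(config.seed)

    p_rounds, lfc_rounds, sig_rounds, bm_rounds, se_rounds = [], [], [], [], []
    design = None
    for r in range(config.de_n_resamplings):
        removed = all_samples[rng.integers(len(all_samples))]
        sa = [s for s in samples_a if s != removed]
        sb = [s for s in samples_b if s != removed]
        try:
            ca, cb, design = aggregate_pseudobulk(
                counts, cell_meta, cell_type, sa, sb, config,
                seed=int(round_seeds[r] % (2**31)),
            )
        except ValueError as exc:
            logger.warning("LOO round %d skipped: %s", r, exc)
            continue
        res = nb_wald_test(ca, cb, counts.genes, config)
        p_rounds.append(res["p"].to_numpy())
        lfc_rounds.append(res["log2fc"].to_numpy())
        bm_rounds.append(res["base_mean"].to_numpy())
        se_rounds.append(res["se"].to_numpy())
        sig_rounds.append(
            (
                (res["padj"] < config.de_padj)
                & (res["log2fc"].abs() > config.de_lfc)
            ).to_numpy()
        )
    if len(p_rounds) < config.de_n_resamplings / 2:
        raise RuntimeError(
            f"only {len(p_rounds)}/{config.de_n_resamplings} LOO rounds succeeded"
        )
    p_med = np.nanmedian(np.stack(p_rounds), axis=0)
    lfc_med = np.median(np.stack(lfc_rounds), axis=0)
    support = np.mean(np.stack(sig_rounds), axis=0)
    tested = ~np.isnan(p_med)
    padj = np.full(len(p_med), np.nan)
    if tested.any():
        padj[tested] = multipletests(p_med[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": counts.genes,
            "base_mean": np.median(np.stack(bm_rounds), axis=0),
            "log2fc": lfc_med,
            "se": np.median(np.stack(se_rounds), axis=0),
            "p": p_med,
            "padj": padj,
            "support": support,
        }
    )
    out["significant"] = (out["padj"] < config.de_padj) & (
        out["log2fc"].abs() > config.de_lfc
    )
    return out, design
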