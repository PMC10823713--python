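"""Synthetic multi-condition single-cell cohorts with planted, known effects.

The generator emulates the structure of a bone-metastasis case/control study:
several sample conditions (solid metastatic tissue, involved and distal
marrow, benign marrow controls), a handful of patients per condition, and a
shared set of cell types whose per-sample proportions are drawn from a
condition-specific Dirichlet. On top of a negative-binomial expression
baseline it plants every effect the downstream statistics are meant to
detect:

* condition-specific composition shifts (proportion multipliers),
* cell-type marker genes (fold-elevated within one type),
* a signature gene module elevated in one (condition, cell type) stratum,
* differentially expressed genes between two conditions within one type,
* ligand-receptor couplings (ligand elevated in a source type, receptor in a
  target type),
* flagged QC-failure cells (low UMI, high mitochondrial fraction, high
  doublet score).

Every planted effect is reported in a truth record so tests can measure
recovery without re-deriving the ground truth. Counts are gene-wise negative
binomial with mean ``profile * cell size factor`` and variance
``mu + mu^2 / theta`` (gamma-Poisson mixture).

Defaults mirror the study design (9 BoneMet, 4 Involved, 4 Distal, 9 Benign
samples) at desk scale; cell and gene counts are documented in the methods
note as the package's simulation sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import CONDITIONS, CountMatrix

__all__ = [
    "CohortSpec",
    "SurvivalCohortSpec",
    "simulate_cohort",
    "simulate_survival_cohort",
    "simulate_nb_pseudobulk",
]


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``condition_multipliers`` plant composition shifts: per condition, a
    mapping cell type -> multiplicative factor applied to the base proportion
    before renormalization. ``lr_couplings`` are (source type, target type,
    fold) triples; the generator assigns one ligand and one receptor gene per
    coupling, elevated fold-x in the source / target type respectively.
    """

    conditions: dict[str, int] = field(
        default_factory=lambda: {"BoneMet": 9, "Involved": 4, "Distal": 4, "Benign": 9}
    )
    cells_per_sample: tuple[int, int] = (300, 600)
    cell_types: tuple[str, ...] = ("NaiveT", "CTL", "Treg", "Mono", "TAM", "MSC")
    base_proportions: tuple[float, ...] = (0.24, 0.20, 0.06, 0.26, 0.12, 0.12)
    dirichlet_concentration: float = 60.0
    condition_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "BoneMet": {"TAM": 3.0, "Treg": 2.0, "NaiveT": 0.4}
        }
    )
    n_genes: int = 300
    mean_log_mu: float = 0.0
    mean_log_sigma: float = 1.0
    target_umi: float = 3000.0
    nb_theta: float = 2.0
    size_factor_sigma: float = 0.3
    # planted effects
    n_markers_per_type: int = 5
    marker_fold: float = 8.0
    signature_size: int = 8
    signature_fold: float = 2.0
    signature_condition: str = "BoneMet"
    signature_cell_type: str = "CTL"
    n_de_genes: int = 20
    de_log2fc: float = 2.0
    de_conditions: tuple[str, str] = ("BoneMet", "Benign")
    de_cell_type: str = "Mono"
    lr_couplings: tuple[tuple[str, str, float], ...] = (("TAM", "Treg", 5.0),)
    # embedding layout
    embedding_radius: float = 10.0
    embedding_sd: float = 1.0
    # QC nuisance fractions (disjoint flagged cells)
    frac_low_umi: float = 0.05
    frac_high_mito: float = 0.03
    frac_high_doublet: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if len(self.base_proportions) != len(self.cell_types):
            raise ValueError("base_proportions must match cell_types length")
        if abs(sum(self.base_proportions) - 1.0) > 1e-8:
            raise ValueError("base_proportions must sum to 1")
        if self.nb_theta <= 0:
            raise ValueError("nb_theta must be positive")
        if min(self.cells_per_sample) < 1:
            raise ValueError("cells_per_sample must request at least one cell")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        for cond in self.condition_multipliers:
            if cond not in self.conditions:
                raise ValueError(f"multiplier for unknown condition {cond!r}")
            unknown_t = set(self.condition_multipliers[cond]) - set(self.cell_types)
            if unknown_t:
                raise ValueError(f"multiplier for unknown cell types {sorted(unknown_t)}")
        needed = (
            len(self.cell_types) * self.n_markers_per_type
            + self.signature_size
            + self.n_de_genes
            + 2 * len(self.lr_couplings)
        )
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {needed} planted genes"
            )


def _condition_proportions(spec: CohortSpec) -> dict[str, np.ndarray]:
    """Renormalized true type proportions per condition."""
    base = np.asarray(spec.base_proportions, dtype=float)
    out = {}
    for cond in spec.conditions:
        mult = np.ones_like(base)
        for t, m in spec.condition_multipliers.get(cond, {}).items():
            mult[spec.cell_types.index(t)] = m
        p = base * mult
        out[cond] = p / p.sum()
    return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def simulate_cohort(spec: CohortSpec):
    """Generate ``(CountMatrix, cell_meta, sample_meta, truth)``.

    The truth record is a plain dict listing every planted effect:
    condition-level type proportions, marker/signature/DE/LR gene
    assignments, and the barcodes flagged for each QC failure mode.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    types = list(spec.cell_types)
    n_types = len(types)

    # --- gene bookkeeping: planted genes occupy the leading block -----------
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    cursor = 0
    marker_genes = {}
    for t in types:
        marker_genes[t] = genes[cursor : cursor + spec.n_markers_per_type]
        cursor += spec.n_markers_per_type
    signature_genes = genes[cursor : cursor + spec.signature_size]
    cursor += spec.signature_size
    de_genes = genes[cursor : cursor + spec.n_de_genes]
    cursor += spec.n_de_genes
    lr_assignments = []
    for src, tgt, fold in spec.lr_couplings:
        lig, rec = genes[cursor], genes[cursor + 1]
        cursor += 2
        lr_assignments.append(
            {"ligand": lig, "receptor": rec, "source": src, "target": tgt, "fold": fold}
        )

    # --- per-type mean profiles --------------------------------------------
    base_mean = rng.lognormal(spec.mean_log_mu, spec.mean_log_sigma, spec.n_genes)
    base_mean *= spec.target_umi / base_mean.sum()
    profiles = np.tile(base_mean, (n_types, 1))  # types x genes
    gidx = {g: i for i, g in enumerate(genes)}
    for ti, t in enumerate(types):
        for g in marker_genes[t]:
            profiles[ti, gidx[g]] *= spec.marker_fold
    for rec in lr_assignments:
        profiles[types.index(rec["source"]), gidx[rec["ligand"]]] *= rec["fold"]
        profiles[types.index(rec["target"]), gidx[rec["receptor"]]] *= rec["fold"]

    # DE genes: half up, half down in de_conditions[0] within de_cell_type
    de_lfc = {}
    for k, g in enumerate(de_genes):
        de_lfc[g] = spec.de_log2fc if k % 2 == 0 else -spec.de_log2fc

    cond_props = _condition_proportions(spec)
    centers = {
        t: (
            spec.embedding_radius * np.cos(2 * np.pi * k / n_types),
            spec.embedding_radius * np.sin(2 * np.pi * k / n_types),
        )
        for k, t in enumerate(types)
    }

    blocks, meta_rows, sample_rows = [], [], []
    sample_counter = 0
    for cond, n_samples in spec.conditions.items():
        for _ in range(n_samples):
            sample_counter += 1
            sid = f"S{sample_counter:02d}_{cond}"
            sample_rows.append((sid, f"P{sample_counter:02d}", cond))
            n_cells = int(rng.integers(spec.cells_per_sample[0], spec.cells_per_sample[1] + 1))
            props = rng.dirichlet(spec.dirichlet_concentration * cond_props[cond])
            type_idx = rng.choice(n_types, size=n_cells, p=props)
            size = rng.lognormal(0.0, spec.size_factor_sigma, n_cells)
            mean = profiles[type_idx] * size[:, None]  # cells x genes
            # condition+type specific planted effects
            if cond == spec.signature_condition:
                mask = type_idx == types.index(spec.signature_cell_type)
                cols = [gidx[g] for g in signature_genes]
                mean[np.ix_(mask, cols)] *= spec.signature_fold
            if cond == spec.de_conditions[0]:
                mask = type_idx == types.index(spec.de_cell_type)
                for g, lfc in de_lfc.items():
                    mean[mask, gidx[g]] *= 2.0 ** lfc
            counts = _nb_counts(rng, mean, spec.nb_theta)  # cells x genes
            cx = np.array([centers[types[i]][0] for i in type_idx])
            cy = np.array([centers[types[i]][1] for i in type_idx])
            ex = cx + rng.normal(0, spec.embedding_sd, n_cells)
            ey = cy + rng.normal(0, spec.embedding_sd, n_cells)
            barcodes = [f"{sid}:C{j:05d}" for j in range(n_cells)]
            blocks.append(counts)
            meta_rows.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "sample_id": sid,
                        "cluster": [types[i] for i in type_idx],
                        "embed_x": ex,
                        "embed_y": ey,
                    }
                )
            )

    counts_all = np.vstack(blocks)  # cells x genes
    meta = pd.concat(meta_rows, ignore_index=True)
    n_total = len(meta)

    # --- QC nuisance: disjoint flagged subsets ------------------------------
    n_low = int(round(spec.frac_low_umi * n_total))
    n_mito = int(round(spec.frac_high_mito * n_total))
    n_doub = int(round(spec.frac_high_doublet * n_total))
    flagged = rng.choice(n_total, size=n_low + n_mito + n_doub, replace=False)
    low_idx = flagged[:n_low]
    mito_idx = flagged[n_low : n_low + n_mito]
    doub_idx = flagged[n_low + n_mito :]

    # thin flagged low-UMI cells below the 700-UMI gate (guaranteed failure)
    for i in low_idx:
        target = int(rng.integers(100, 650))
        while counts_all[i].sum() >= 700:
            keep_p = min(target / counts_all[i].sum(), 0.95)
            counts_all[i] = rng.binomial(counts_all[i], keep_p)

    # baseline cells are guaranteed to pass every gate so the planted flags
    # are the exact removal set: bounded mito/doublet baselines, UMI floor
    unflagged = np.setdiff1d(np.arange(n_total), flagged)
    for i in unflagged:
        deficit = 700 - counts_all[i].sum()
        if deficit > 0:
            counts_all[i, np.argmax(counts_all[i])] += deficit

    mito_frac = 0.18 * rng.beta(2.0, 5.0, n_total)  # baseline ~5%, <0.18
    mito_frac[mito_idx] = rng.uniform(0.25, 0.60, n_mito)
    doublet = rng.uniform(0.0, 0.20, n_total)
    doublet[doub_idx] = rng.uniform(0.45, 0.90, n_doub)

    meta["total_umi"] = counts_all.sum(axis=1)
    meta["mito_frac"] = mito_frac
    meta["doublet_score"] = doublet
    meta = meta[
        [
            "barcode",
            "sample_id",
            "cluster",
            "embed_x",
            "embed_y",
            "total_umi",
            "mito_frac",
            "doublet_score",
        ]
    ]

    cm = CountMatrix(genes, meta["barcode"].tolist(), sp.csr_matrix(counts_all.T))
    sample_meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "condition"]
    )
    truth = {
        "condition_fractions": {
            cond: dict(zip(types, map(float, p))) for cond, p in cond_props.items()
        },
        "marker_genes": marker_genes,
        "marker_fold": spec.marker_fold,
        "signature": {
            "genes": signature_genes,
            "condition": spec.signature_condition,
            "cell_type": spec.signature_cell_type,
            "fold": spec.signature_fold,
        },
        "de": {
            "cell_type": spec.de_cell_type,
            "conditions": list(spec.de_conditions),
            "log2fc": de_lfc,
        },
        "lr_couplings": lr_assignments,
        "qc": {
            "low_umi": meta["barcode"].iloc[low_idx].tolist(),
            "high_mito": meta["barcode"].iloc[mito_idx].tolist(),
            "high_doublet": meta["barcode"].iloc[doub_idx].tolist(),
        },
    }
    return cm, meta, sample_meta, truth


@dataclass
class SurvivalCohortSpec:
    """Bulk survival cohort with a signature-linked hazard.

    Signature genes load on a latent per-patient activity; patients in the top
    activity quartile have ``hazard_ratio`` times the baseline event hazard of
    the bottom quartile (middle half at the geometric mean). ``confound_age``
    optionally tilts age with activity to exercise covariate adjustment.
    """

    n_patients: int = 200
    n_genes: int = 100
    signature_size: int = 10
    loading: float = 1.0
    noise_sd: float = 1.0
    hazard_ratio: float = 2.0
    baseline_hazard: float = 1.0 / 365.0
    censoring_rate: float = 0.30
    confound_age: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.signature_size < 1:
            raise ValueError("signature must contain at least one gene")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size exceeds n_genes")


def simulate_survival_cohort(spec: SurvivalCohortSpec):
    """Generate a bulk cohort table plus truth record.

    Returns a DataFrame with ``patient_id, time, event, age, stage`` and one
    column per gene, and a dict holding the latent activity, the quartile
    group labels, and the planted signature genes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    activity = rng.normal(0.0, 1.0, n)
    genes = [f"B{i:04d}" for i in range(spec.n_genes)]
    sig_genes = genes[: spec.signature_size]
    expr = rng.normal(0.0, spec.noise_sd, (n, spec.n_genes))
    expr[:, : spec.signature_size] += spec.loading * activity[:, None]

    q1, q3 = np.quantile(activity, [0.25, 0.75])
    group = np.where(activity >= q3, "high", np.where(activity <= q1, "low", "mid"))
    mult = {"low": 1.0, "mid": np.sqrt(spec.hazard_ratio), "high": spec.hazard_ratio}
    hazard = spec.baseline_hazard * np.array([mult[g] for g in group])
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        # independent exponential censoring tuned to the requested marginal rate
        c_rate = hazard.mean() * spec.censoring_rate / (1 - spec.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    age = 60 + 10 * rng.normal(size=n) + spec.confound_age * activity
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.4, 0.25, 0.2, 0.15])

    cohort = pd.DataFrame(
        {
            "patient_id": [f"PT{i:04d}" for i in range(n)],
            "time": np.maximum(time, 1e-3),
            "event": event,
            "age": age,
            "stage": stage,
        }
    )
    cohort = pd.concat(
        [cohort, pd.DataFrame(expr, columns=genes, index=cohort.index)], axis=1
    )
    truth = {
        "signature_genes": sig_genes,
        "activity": activity.tolist(),
        "group": group.tolist(),
        "hazard_ratio": spec.hazard_ratio,
    }
    return cohort, truth


def simulate_nb_pseudobulk(
    n_genes: int = 2000,
    n_per_group: tuple[int, int] = (8, 8),
    theta: float = 10.0,
    n_planted: int = 100,
    log2fc: float = 2.0,
    mean_log_mu: float = 4.0,
    mean_log_sigma: float = 1.5,
    libsize_sigma: float = 0.25,
    seed: int = 0,
):
    """Sample-level negative-binomial pseudobulk counts for two groups.

    Emulates the aggregated per-sample counts a pseudobulk DE test consumes:
    gene means are lognormal, library sizes vary lognormally across samples,
    and ``n_planted`` genes carry a true ``log2fc`` in group B (alternating
    sign). Returns ``(counts_a, counts_b, planted)`` where counts are
    genes x samples integer arrays and ``planted`` maps gene index -> signed
    log2 fold change.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean_log_mu, mean_log_sigma, n_genes)
    lib = rng.lognormal(0.0, libsize_sigma, sum(n_per_group))
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    lfc = np.zeros(n_genes)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    lfc[planted_idx] = signs * log2fc
    mean_a = base[:, None] * lib[: n_per_group[0]][None, :]
    mean_b = (base * 2.0 ** lfc)[:, None] * lib[n_per_group[0] :][None, :]
    counts_a = _nb_counts(rng, mean_a, theta)
    counts_b = _nb_counts(rng, mean_b, theta)
    planted = {int(i): float(lfc[i]) for i in planted_idx}
    return counts_a, counts_b, planted
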