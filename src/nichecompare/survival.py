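"""Signature-stratified survival analysis on a bulk cohort.

Patients are scored by the mean expression of a gene signature and split
into the top and bottom quartiles (floor(0.25 n) each; the middle half is
excluded). The two strata are compared with a two-sided log-rank test and
Kaplan-Meier curves, optionally adjusted for age and disease stage in a Cox
proportional-hazards model. Stability of the signature itself is assessed by
a gene-subset bootstrap: 200 rounds each draw a random subset of the
signature (default 80% of the genes, without replacement), re-stratify and
re-test, and the 0.90th empirical quantile of the bootstrap p-values is
reported (linear/type-7 interpolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .datatypes import AnalysisConfig, GeneSignature, drop_missing_genes

logger = logging.getLogger("nichecompare")


def stratify_by_signature(cohort: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Assign 'high' / 'low' / 'excluded' by signature-score quartiles.

    Score = mean expression over signature genes present in the cohort; the
    top and bottom floor(0.25 n) patients form the high and low groups. Ties
    at a boundary are broken by stable patient-id order. Raises when no
    signature gene is present, when n < 8, or when all scores are identical.
    """
    if len(cohort) < 8:
        raise ValueError("cohort too small to stratify (n < 8)")
    gene_cols = [c for c in cohort.columns
                 if c not in ("patient_id", "time", "event", "age", "stage")]
    present = drop_missing_genes(signature.genes, gene_cols, f"signature {signature.name}")
    if not present:
        raise ValueError(
            f"no genes of signature {signature.name!r} in cohort "
            f"(missing: {signature.genes})"
        )
    score = cohort[present].mean(axis=1)
    if score.nunique() == 1:
        raise ValueError("all signature scores identical; cannot stratify")
    k = int(np.floor(0.25 * len(cohort)))
    order = (
        pd.DataFrame({"score": score, "pid": cohort["patient_id"]})
        .sort_values(["score", "pid"], kind="mergesort")
        .index
    )
    group = pd.Series("excluded", index=cohort.index, name="group")
    group.loc[order[:k]] = "low"
    group.loc[order[-k:]] = "high"
    return group


@dataclass
class SurvivalResult:
    groups: pd.Series
    logrank_p: float
    km_curves: pd.DataFrame  # group, time, survival
    cox_hr: float = np.nan
    cox_ci: tuple = (np.nan, np.nan)
    cox_p: float = np.nan
    cox_converged: bool = False
    cox_diagnostics: str = ""
    bootstrap_p: np.ndarray = field(default_factory=lambda: np.array([]))
    bootstrap_quantile: float = np.nan


def logrank_km(cohort: pd.DataFrame, groups: pd.Series) -> tuple[float, pd.DataFrame]:
    """Two-sided log-rank p and Kaplan-Meier curves for high vs low strata.

    Returns ``(p, curves)``; p is NaN (untestable) when no events occurred.
    """
    hi = groups == "high"
    lo = groups == "low"
    if not hi.any() or not lo.any():
        raise ValueError("both groups must be non-empty")
    if cohort.loc[hi | lo, "event"].sum() == 0:
        logger.warning("zero events in both strata; log-rank untestable")
        p = np.nan
    else:
        res = logrank_test(
            cohort.loc[hi, "time"], cohort.loc[lo, "time"],
            event_observed_A=cohort.loc[hi, "event"],
            event_observed_B=cohort.loc[lo, "event"],
        )
        p = float(res.p_value)
    curves = []
    kmf = KaplanMeierFitter()
    for name, mask in (("high", hi), ("low", lo)):
        kmf.fit(cohort.loc[mask, "time"], cohort.loc[mask, "event"])
        sf = kmf.survival_function_
        curves.append(
            pd.DataFrame(
                {"group": name, "time": sf.index.to_numpy(),
                 "survival": sf.iloc[:, 0].to_numpy()}
            )
        )
    return p, pd.concat(curves, ignore_index=True)


def cox_adjusted(cohort: pd.DataFrame, groups: pd.Series):
    """Cox PH fit of the high-vs-low indicator adjusted for age and stage.

    Stage is one-hot encoded against its first (sorted) level as reference.
    Non-convergence or separation is returned as a flagged result, not an
    exception: ``(hr, (ci_lo, ci_hi), p, converged, diagnostics)``.
    """
    mask = groups.isin(["high", "low"])
    df = cohort.loc[mask, ["time", "event", "age", "stage"]].copy()
    df["group_high"] = (groups[mask] == "high").astype(float)
    if df["group_high"].nunique() < 2:
        raise ValueError("group indicator is constant; no contrast to estimate")
    stage_levels = sorted(df["stage"].astype(str).unique())
    for lev in stage_levels[1:]:
        df[f"stage_{lev}"] = (df["stage"].astype(str) == lev).astype(float)
    df = df.drop(columns="stage")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("Cox fit failed: %s", exc)
        return np.nan, (np.nan, np.nan), np.nan, False, str(exc)
    hr = float(np.exp(cph.params_["group_high"]))
    ci = cph.confidence_intervals_.loc["group_high"]
    p = float(cph.summary.loc["group_high", "p"])
    return hr, (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))), p, True, ""


def bootstrap_stability(
    cohort: pd.DataFrame,
    signature: GeneSignature,
    config: AnalysisConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Gene-subset bootstrap of the log-rank analysis.

    ``surv_n_boot`` rounds (default 200) each draw
    ``max(2, round(surv_boot_frac * n_genes))`` signature genes without
    replacement, re-stratify, and re-run the log-rank test. Returns the
    p-value vector and its ``surv_report_q`` (default 0.90) empirical
    quantile under linear (type-7) interpolation. Rounds whose subset has no
    present genes are redrawn (bounded retries).
    """
    config = config or AnalysisConfig()
    if len(signature.genes) < 3:
        raise ValueError("bootstrap stability needs a signature with >=3 genes")
    rng = np.random.default_rng(config.seed)
    gene_cols = set(cohort.columns)
    n_sub = max(2, int(round(config.surv_boot_frac * len(signature.genes))))
    ps = np.empty(config.surv_n_boot)
    for i in range(config.surv_n_boot):
        for _ in range(100):
            subset = list(rng.choice(signature.genes, size=n_sub, replace=False))
            if any(g in gene_cols for g in subset):
                break
        else:
            raise RuntimeError("could not draw a gene subset present in the cohort")
        sub_sig = GeneSignature(f"{signature.name}_boot{i}", subset)
        groups = stratify_by_signature(cohort, sub_sig)
        ps[i], _ = logrank_km(cohort, groups)
    return ps, float(np.quantile(ps, config.surv_report_q, method="linear"))


def run_survival(
    cohort: pd.DataFrame,
    signature: GeneSignature,
    config: AnalysisConfig | None = None,
    with_bootstrap: bool = True,
) -> SurvivalResult:
    """Full survival pipeline: stratify, log-rank/KM, Cox, bootstrap."""
    config = config or AnalysisConfig()
    groups = stratify_by_signature(cohort, signature)
    p, curves = logrank_km(cohort, groups)
    hr, ci, cox_p, conv, diag = cox_adjusted(cohort, groups)
    result = SurvivalResult(groups, p, curves, hr, ci, cox_p, conv, diag)
    if with_bootstrap and len(signature.genes) >= 3:
        result.bootstrap_p, result.bootstrap_quantile = bootstrap_stability(
            cohort, signature, config
        )
    return result
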