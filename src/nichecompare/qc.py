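"""Cell-level quality-control gating.

A cell is retained iff total UMI >= ``min_umi`` AND mitochondrial fraction
<= ``max_mito`` AND doublet score <= ``max_doublet``; removal criteria use
strict inequalities, so boundary cells pass. Cells failing several rules are
attributed to the first failing rule in the fixed order (UMI, mito, doublet)
for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, CountMatrix, validate_cell_meta


@dataclass
class QCReport:
    """Per-sample removal counts, one row per sample plus thresholds used."""

    table: pd.DataFrame  # sample_id, n_input, n_low_umi, n_high_mito, n_doublet, n_retained
    min_umi: int
    max_mito: float
    max_doublet: float

    def total_retained(self) -> int:
        return int(self.table["n_retained"].sum())


def apply_qc(
    counts: CountMatrix, meta: pd.DataFrame, config: AnalysisConfig | None = None
):
    """Filter cells by the three QC rules.

    Returns ``(filtered_counts, filtered_meta, QCReport)``. The metadata must
    cover exactly the matrix barcodes. mito_frac and doublet_score are
    consumed from the metadata (scores are inputs, not computed here).
    """
    config = config or AnalysisConfig()
    validate_cell_meta(meta, counts)
    meta = meta.set_index("barcode").loc[counts.cells].reset_index()

    umi = meta["total_umi"].to_numpy(dtype=float)
    mito = meta["mito_frac"].to_numpy(dtype=float)
    doub = meta["doublet_score"].to_numpy(dtype=float)

    fail_umi = umi < config.min_umi
    fail_mito = mito > config.max_mito
    fail_doub = doub > config.max_doublet
    keep = ~(fail_umi | fail_mito | fail_doub)

    # attribute multi-rule failures to the first failing rule, in fixed order
    first_mito = fail_mito & ~fail_umi
    first_doub = fail_doub & ~fail_umi & ~fail_mito

    rows = []
    for sid, grp in meta.groupby("sample_id", sort=True):
        idx = grp.index.to_numpy()
        rows.append(
            {
                "sample_id": sid,
                "n_input": len(idx),
                "n_low_umi": int(fail_umi[idx].sum()),
                "n_high_mito": int(first_mito[idx].sum()),
                "n_doublet": int(first_doub[idx].sum()),
                "n_retained": int(keep[idx].sum()),
            }
        )
    report = QCReport(
        pd.DataFrame(rows),
        config.min_umi,
        config.max_mito,
        config.max_doublet,
    )
    filtered = counts.subset_cells(keep)
    return filtered, meta.loc[keep].reset_index(drop=True), report
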