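"""Core containers shared across the pipeline.

The package operates on four kinds of objects:

* :class:`CountMatrix` — a sparse genes x cells matrix of raw UMI counts with
  gene symbols and cell barcodes.
* per-cell and per-sample metadata tables (plain :class:`pandas.DataFrame`
  objects validated by :func:`validate_cell_meta` / :func:`validate_sample_meta`).
* :class:`GeneSignature` — a named, de-duplicated gene set.
* :class:`AnalysisConfig` — every numeric threshold used downstream, in one
  place, so that a single YAML file reproduces a full analysis.

"Normalized expression" means the same thing everywhere in the package:
per-cell library-size scaling to 10,000 counts followed by ``log(1 + x)``
(:meth:`CountMatrix.normalized`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("nichecompare")

#: Recognized sample conditions (study fractions plus primary-tumor fractions).
CONDITIONS = (
    "Healthy",
    "Benign",
    "Involved",
    "Distal",
    "BoneMet",
    "Primary",
    "AdjNormal",
)

CELL_META_COLUMNS = (
    "barcode",
    "sample_id",
    "cluster",
    "embed_x",
    "embed_y",
    "total_umi",
    "mito_frac",
    "doublet_score",
)

SAMPLE_META_COLUMNS = ("sample_id", "patient_id", "condition")


class StructuralError(ValueError):
    """Raised when inputs violate a structural contract (dims, ids, schema)."""


@dataclass
class CountMatrix:
    """Sparse raw UMI count matrix, genes x cells.

    Parameters
    ----------
    genes
        Gene symbols, unique (duplicates must be disambiguated before
        construction; see :func:`nichecompare.io.read_counts_mtx`).
    cells
        Cell barcodes, unique.
    counts
        ``scipy.sparse`` matrix of shape ``(len(genes), len(cells))`` with
        non-negative integral entries.
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise StructuralError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise StructuralError("duplicate gene symbols in CountMatrix")
        if len(set(self.cells)) != len(self.cells):
            raise StructuralError("duplicate cell barcodes in CountMatrix")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise StructuralError("negative entries in count matrix")
            if not np.allclose(data, np.round(data)):
                raise StructuralError("non-integral entries in count matrix")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def cell_totals(self) -> np.ndarray:
        """Per-cell total UMI (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, keep: Sequence) -> "CountMatrix":
        """Subset to barcodes in ``keep`` (bool mask or barcode list), order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {b: i for i, b in enumerate(self.cells)}
            missing = [b for b in keep if b not in pos]
            if missing:
                raise StructuralError(f"unknown barcodes: {missing[:5]}...")
            idx = np.array([pos[b] for b in keep], dtype=int)
        return CountMatrix(
            self.genes, [self.cells[i] for i in idx], self.counts[:, idx]
        )

    def subset_genes(self, keep: Sequence[str]) -> "CountMatrix":
        pos = self.gene_index()
        idx = np.array([pos[g] for g in keep], dtype=int)
        return CountMatrix(list(keep), self.cells, self.counts[idx, :])

    def normalized(self, target_sum: float = 1e4) -> np.ndarray:
        """Dense normalized expression: log1p of per-cell CP10K scaling.

        Cells with zero total counts get all-zero normalized values.
        """
        totals = self.cell_totals().astype(float)
        scale = np.divide(
            target_sum, totals, out=np.zeros_like(totals), where=totals > 0
        )
        dense = np.asarray(self.counts.todense(), dtype=float)
        return np.log1p(dense * scale[np.newaxis, :])


@dataclass
class GeneSignature:
    """Named gene set; duplicates removed preserving first-seen order."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")


def validate_cell_meta(meta: pd.DataFrame, counts: CountMatrix | None = None) -> None:
    """Check the per-cell metadata contract.

    Every barcode must be unique, fractions must lie in [0, 1], and, when a
    count matrix is supplied, the barcode sets must match exactly.
    """
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise StructuralError(f"cell metadata missing columns {missing}")
    if meta["barcode"].duplicated().any():
        raise StructuralError("duplicate barcodes in cell metadata")
    for col in ("mito_frac", "doublet_score"):
        vals = meta[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise StructuralError(f"{col} outside [0, 1]")
    if counts is not None and set(meta["barcode"]) != set(counts.cells):
        raise StructuralError("cell metadata barcodes do not match count matrix")


def validate_sample_meta(samples: pd.DataFrame, meta: pd.DataFrame | None = None) -> None:
    missing = [c for c in SAMPLE_META_COLUMNS if c not in samples.columns]
    if missing:
        raise StructuralError(f"sample metadata missing columns {missing}")
    if samples["sample_id"].duplicated().any():
        raise StructuralError("duplicate sample_id in sample metadata")
    bad = set(samples["condition"]) - set(CONDITIONS)
    if bad:
        raise StructuralError(f"unknown conditions {sorted(bad)}; allowed {CONDITIONS}")
    if meta is not None:
        orphan = set(meta["sample_id"]) - set(samples["sample_id"])
        if orphan:
            raise StructuralError(f"cells reference unknown samples {sorted(orphan)}")


@dataclass
class AnalysisConfig:
    """All thresholds of the comparative pipeline, with study defaults.

    QC removal uses strict inequalities (a cell at exactly the boundary is
    retained); every other threshold is documented at its consuming function.
    """

    # QC gates
    min_umi: int = 700
    max_mito: float = 0.20
    max_doublet: float = 0.40
    # marker detection
    marker_z: float = 3.0
    # cluster-based composition
    min_cells_composition: int = 50
    # cluster-free composition
    grid: int = 400
    grid_padding: float = 0.02
    # pseudobulk DE
    de_min_cells: int = 10
    de_max_cells: int = 320
    de_n_resamplings: int = 100
    de_padj: float = 0.05
    de_lfc: float = 1.5
    de_min_mean_norm: float = 1.0  # independent-filtering analogue
    # ligand-receptor
    lr_expr_ratio: float = 0.10
    lr_n_perm: int = 1000
    lr_p: float = 0.05
    lr_ligand_z: float = 4.0
    lr_receptor_z: float = 0.0
    lr_min_cells: int = 10
    # survival
    surv_quantile: float = 0.25
    surv_n_boot: int = 200
    surv_report_q: float = 0.90
    surv_boot_frac: float = 0.80
    # shared
    pseudobulk_min_cells: int = 10
    n_top_genes_distance: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "seed":
                continue
            if v <= 0 and f.name not in ("lr_receptor_z",):
                raise ValueError(f"config field {f.name} must be positive, got {v}")
        for name in (
            "max_mito",
            "max_doublet",
            "de_padj",
            "lr_expr_ratio",
            "lr_p",
            "surv_quantile",
            "surv_report_q",
            "surv_boot_frac",
            "grid_padding",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"config field {name} must be in (0, 1), got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def drop_missing_genes(
    requested: Iterable[str], available: Iterable[str], what: str
) -> list[str]:
    """Intersect a requested gene list with the matrix genes, warning on drops."""
    avail = set(available)
    requested = list(requested)
    present = [g for g in requested if g in avail]
    n_missing = len(requested) - len(present)
    if n_missing:
        missing = [g for g in requested if g not in avail]
        logger.warning(
            "%s: %d/%d genes absent from matrix (e.g. %s)",
            what,
            n_missing,
            len(requested),
            ", ".join(missing[:5]),
        )
    return present
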