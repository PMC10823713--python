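"""Readers and writers for the package's on-disk formats.

Inputs follow the 10x-style conventions: a Matrix Market triple
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``) for counts, CSV for
cell/sample metadata and ligand-receptor pairs, GMT for gene sets, and YAML
for :class:`~nichecompare.datatypes.AnalysisConfig`. All module outputs are
written as TSV through :func:`write_table`, which fixes float formatting and
row order so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datatypes import (
    AnalysisConfig,
    CountMatrix,
    GeneSignature,
    StructuralError,
    validate_cell_meta,
    validate_sample_meta,
)

logger = logging.getLogger("nichecompare")


def _disambiguate(symbols: list[str]) -> list[str]:
    """Suffix repeated symbols pandas-style: X, X.1, X.2, ..."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        n = seen.get(s, 0)
        out.append(s if n == 0 else f"{s}.{n}")
        seen[s] = n + 1
    return out


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style MTX triple into a :class:`CountMatrix`.

    The features file may have one column (symbol) or two or more (id, symbol,
    ...); symbols are taken from the second column when present. Duplicate
    symbols are disambiguated deterministically with ``.1``, ``.2`` suffixes.
    """
    try:
        counts = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - report parse location to the user
        raise StructuralError(f"malformed MTX file {matrix_path}: {exc}") from exc
    counts = sp.csr_matrix(counts)
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    symbols = features.iloc[:, 1 if features.shape[1] > 1 else 0].tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].tolist()
    if counts.shape != (len(symbols), len(barcodes)):
        raise StructuralError(
            f"MTX header {counts.shape} does not match {len(symbols)} features "
            f"x {len(barcodes)} barcodes"
        )
    return CountMatrix(_disambiguate(symbols), barcodes, counts)


def write_counts_mtx(cm: CountMatrix, out_dir) -> None:
    """Write the MTX triple; exact integer round-trip with :func:`read_counts_mtx`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(out / "matrix.mtx"), sp.coo_matrix(cm.counts.astype(int)), field="integer"
    )
    (out / "features.tsv").write_text("".join(f"{g}\n" for g in cm.genes))
    (out / "barcodes.tsv").write_text("".join(f"{b}\n" for b in cm.cells))


def read_counts_dir(path) -> CountMatrix:
    p = Path(path)
    return read_counts_mtx(p / "matrix.mtx", p / "features.tsv", p / "barcodes.tsv")


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file: one tab-separated line per set (name, description, genes...)."""
    sigs = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise StructuralError(
                    f"{path}:{i}: GMT line needs name, description and >=1 gene"
                )
            sigs.append(GeneSignature(parts[0], parts[2:]))
    return sigs


def write_gmt(signatures: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, "-"] + s.genes) + "\n")


def read_lr_table(path, ligand_col: str = "ligand", receptor_col: str = "receptor") -> pd.DataFrame:
    """Read a CellPhoneDB-style ligand-receptor pair CSV.

    Returns a DataFrame with columns ``ligand`` and ``receptor``; duplicate
    pairs are dropped keeping first-seen order.
    """
    df = pd.read_csv(path, dtype=str)
    for col in (ligand_col, receptor_col):
        if col not in df.columns:
            raise StructuralError(f"{path}: missing required column {col!r}")
    out = df[[ligand_col, receptor_col]].rename(
        columns={ligand_col: "ligand", receptor_col: "receptor"}
    )
    out = out.dropna()
    out = out[(out["ligand"] != "") & (out["receptor"] != "")]
    out = out.drop_duplicates(ignore_index=True)
    if out.empty:
        logger.warning("%s: ligand-receptor table is empty", path)
    return out


def read_cell_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    validate_cell_meta(meta)
    return meta


def read_sample_meta(path) -> pd.DataFrame:
    samples = pd.read_csv(path)
    validate_sample_meta(samples)
    return samples


def write_table(result: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    """Write a result table as TSV with fixed formatting.

    Floats are rendered at 6 significant digits; rows are sorted by
    ``sort_by`` when given (else left in the caller's documented order), so a
    rerun with the same inputs is byte-identical.
    """
    df = result.copy()
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_survival_cohort(path) -> pd.DataFrame:
    """Read a bulk survival cohort CSV.

    Expected columns: ``patient_id``, ``time``, ``event``, ``age``, ``stage``,
    followed by one column per gene (normalized bulk expression).
    """
    df = pd.read_csv(path)
    required = ["patient_id", "time", "event", "age", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: survival cohort missing columns {missing}")
    if (df["time"] <= 0).any():
        raise StructuralError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise StructuralError("event indicator must be 0/1")
    return df
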