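"""Compositional shift testing between sample conditions.

Two complementary views:

* cluster-based — per-sample cell-type fractions within a major population
  (samples contributing fewer than ``min_cells_composition`` cells of that
  major population are excluded), contrasted with a two-sided Wilcoxon
  rank-sum test and BH correction across cell types within each condition
  pair;
* cluster-free — per-sample 2D kernel density on a provided embedding,
  evaluated on a shared grid (default 400 x 400 over the global bounding box
  plus 2% padding), averaged per condition, and differenced per bin with a
  standardized Wilcoxon statistic (positive = enriched in the first
  condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AnalysisConfig

logger = logging.getLogger("nichecompare")


def sample_fractions(
    cell_meta: pd.DataFrame,
    major_population_map: Mapping[str, str],
    min_cells: int,
) -> pd.DataFrame:
    """Per-sample cell-type fractions within each major population.

    Returns a long DataFrame (sample_id, major, cell_type, n_cells, n_major,
    fraction) containing only samples that pass the major-population cell
    gate for that population.
    """
    df = cell_meta[["sample_id", "cluster"]].copy()
    df["major"] = df["cluster"].map(major_population_map)
    unknown = df.loc[df["major"].isna(), "cluster"].unique()
    if len(unknown):
        logger.warning("cell types without major population dropped: %s", list(unknown))
        df = df.dropna(subset=["major"])
    counts = (
        df.groupby(["sample_id", "major", "cluster"]).size().rename("n_cells").reset_index()
    )
    major_tot = (
        counts.groupby(["sample_id", "major"])["n_cells"].sum().rename("n_major").reset_index()
    )
    counts = counts.merge(major_tot, on=["sample_id", "major"])
    counts = counts[counts["n_major"] >= min_cells].copy()
    counts["fraction"] = counts["n_cells"] / counts["n_major"]
    return counts.rename(columns={"cluster": "cell_type"})


def composition_test(
    cell_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
    major_population_map: Mapping[str, str],
    condition_pairs: Sequence[tuple[str, str]],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Cluster-based composition contrast between condition pairs.

    For every cell type and condition pair, per-sample fractions (within the
    type's major population) are compared with a two-sided Wilcoxon rank-sum
    test; BH correction runs across cell types within each pair. A sample
    absent from a type's fraction table still counts as fraction 0 when it
    passes the major-population gate.
    """
    config = config or AnalysisConfig()
    fracs = sample_fractions(cell_meta, major_population_map, config.min_cells_composition)
    cond = sample_meta.set_index("sample_id")["condition"]
    cell_types = sorted(set(major_population_map))
    rows = []
    for a, b in condition_pairs:
        for ct in cell_types:
            major = major_population_map[ct]
            # samples passing the gate for this major population
            gated = fracs[fracs["major"] == major]
            passing = gated["sample_id"].unique()
            sub = gated[gated["cell_type"] == ct].set_index("sample_id")["fraction"]
            frac_by_sample = pd.Series(0.0, index=passing).add(sub, fill_value=0.0)
            fa = frac_by_sample[frac_by_sample.index.map(cond) == a].to_numpy()
            fb = frac_by_sample[frac_by_sample.index.map(cond) == b].to_numpy()
            row = {
                "cell_type": ct,
                "condition_a": a,
                "condition_b": b,
                "n_a": len(fa),
                "n_b": len(fb),
                "frac_a_median": float(np.median(fa)) if len(fa) else np.nan,
                "frac_b_median": float(np.median(fb)) if len(fb) else np.nan,
            }
            if len(fa) < 2 or len(fb) < 2:
                row.update({"p": np.nan, "tested": False})
            else:
                from .markers import _ranksum_rows

                row.update({"p": float(_ranksum_rows(fa, fb)[0]), "tested": True})
            rows.append(row)
    out = pd.DataFrame(rows)
    out["padj"] = np.nan
    for (a, b), grp in out.groupby(["condition_a", "condition_b"]):
        tested = grp.index[grp["tested"].astype(bool)]
        if len(tested):
            out.loc[tested, "padj"] = multipletests(
                out.loc[tested, "p"].to_numpy(), method="fdr_bh"
            )[1]
    return out


@dataclass
class DensityMaps:
    """Shared-grid KDE maps: per-sample (normalized to sum 1) and per-condition means."""

    grid_x: np.ndarray  # bin centers, length g
    grid_y: np.ndarray
    sample_maps: dict[str, np.ndarray]  # sample_id -> (g, g) array
    condition_maps: dict[str, np.ndarray]
    sample_conditions: dict[str, str]


def _kde_on_grid(x: np.ndarray, y: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) evaluated at grid centers, sum-1 normalized.

    Degenerate samples (zero variance in either axis) fall back to a 2D
    histogram on the same grid, which preserves the argmax-at-the-point
    behaviour a delta distribution should have.
    """
    g = len(gx)
    if np.ptp(x) == 0 or np.ptp(y) == 0 or len(x) < 3:
        ix = np.clip(np.searchsorted(gx, x), 0, g - 1)
        iy = np.clip(np.searchsorted(gy, y), 0, g - 1)
        h = np.zeros((g, g))
        np.add.at(h, (ix, iy), 1.0)
        return h / h.sum()
    kde = stats.gaussian_kde(np.vstack([x, y]), bw_method="silverman")
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(g, g)
    total = dens.sum()
    if total <= 0:
        raise FloatingPointError("degenerate density (all-zero KDE evaluation)")
    return dens / total


def density_maps(
    cell_meta: pd.DataFrame,
    sample_meta: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    config: AnalysisConfig | None = None,
) -> DensityMaps:
    """Per-sample KDE on the shared embedding grid, averaged per condition.

    Samples with fewer than 10 cells are excluded with a warning. The grid is
    the global embedding bounding box padded by ``config.grid_padding`` on
    each side, so it is identical across samples (affine rescaling of the
    embedding rescales the grid with it).
    """
    config = config or AnalysisConfig()
    cond = sample_meta.set_index("sample_id")["condition"]
    if conditions is not None:
        keep_sids = cond[cond.isin(conditions)].index
        cell_meta = cell_meta[cell_meta["sample_id"].isin(keep_sids)]
    x = cell_meta["embed_x"].to_numpy(dtype=float)
    y = cell_meta["embed_y"].to_numpy(dtype=float)
    pad = config.grid_padding
    xlo, xhi = x.min(), x.max()
    ylo, yhi = y.min(), y.max()
    xlo, xhi = xlo - pad * (xhi - xlo), xhi + pad * (xhi - xlo)
    ylo, yhi = ylo - pad * (yhi - ylo), yhi + pad * (yhi - ylo)
    g = config.grid
    gx = np.linspace(xlo, xhi, g)
    gy = np.linspace(ylo, yhi, g)

    sample_maps: dict[str, np.ndarray] = {}
    sample_conditions: dict[str, str] = {}
    for sid, grp in cell_meta.groupby("sample_id", sort=True):
        if len(grp) < 10:
            logger.warning("sample %s has <10 cells; excluded from density maps", sid)
            continue
        sample_maps[sid] = _kde_on_grid(
            grp["embed_x"].to_numpy(float), grp["embed_y"].to_numpy(float), gx, gy
        )
        sample_conditions[sid] = cond[sid]
    condition_maps = {}
    for c in sorted(set(sample_conditions.values())):
        maps = [m for s, m in sample_maps.items() if sample_conditions[s] == c]
        condition_maps[c] = np.mean(maps, axis=0)
    return DensityMaps(gx, gy, sample_maps, condition_maps, sample_conditions)


def density_difference(maps: DensityMaps, condition_a: str, condition_b: str) -> np.ndarray:
    """Per-bin standardized Wilcoxon statistic comparing per-sample densities.

    Positive values mark bins denser in ``condition_a``. Bins where every
    sample density is tied (e.g. all zero) get statistic 0. Requires >=2
    samples per condition.
    """
    a = np.stack([m for s, m in maps.sample_maps.items() if maps.sample_conditions[s] == condition_a])
    b = np.stack([m for s, m in maps.sample_maps.items() if maps.sample_conditions[s] == condition_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("density_difference needs >=2 samples per condition")
    stat = stats.ranksums(
        np.moveaxis(a, 0, -1), np.moveaxis(b, 0, -1), axis=-1
    ).statistic
    return np.nan_to_num(np.asarray(stat, dtype=float))
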