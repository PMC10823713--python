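import numpy as np
import pandas as pd
import pytest

from nichecompare.datatypes import AnalysisConfig
from nichecompare.simulate import CohortSpec, simulate_cohort


def small_spec(**overrides) -> CohortSpec:
    """Desk-scale cohort spec used across tests (fewer cells/genes)."""
    defaults = dict(
        cells_per_sample=(120, 200),
        n_genes=120,
        n_markers_per_type=3,
        signature_size=5,
        n_de_genes=10,
        seed=0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def cohort():
    """One shared small cohort: (CountMatrix, cell_meta, sample_meta, truth)."""
    return simulate_cohort(small_spec(seed=42))


@pytest.fixture(scope="session")
def qc_clean_cohort():
    """Cohort without planted QC failures (all cells pass the gates)."""
    spec = small_spec(
        seed=43, frac_low_umi=1e-9, frac_high_mito=1e-9, frac_high_doublet=1e-9
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def norm_and_meta(qc_clean_cohort):
    """Normalized expression aligned with metadata for marker/LR tests."""
    cm, meta, samples, truth = qc_clean_cohort
    meta = meta.set_index("barcode").loc[cm.cells].reset_index()
    return cm.normalized(), cm.genes, meta, samples, truth
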