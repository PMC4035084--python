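import numpy as np
import pandas as pd
import pytest

from snpcnv.io import VariantCatalogEntry
from snpcnv.simulate import (CnvLocus, SimulationDesign, default_design,
                             default_variant_catalog)


@pytest.fixture(scope="session")
def small_catalog():
    """Three risk SNPs with hand-picked betas/frequencies."""
    return [
        VariantCatalogEntry("rs1", "chr1", 1000, "A", "G", 0.39, 0.4, proxy_r2=0.8),
        VariantCatalogEntry("rs2", "chr2", 2000, "C", "T", 0.14, 0.3, proxy_r2=0.9),
        VariantCatalogEntry("rs3", "chr3", 3000, "G", "A", 0.10, 0.6,
                            proxy_r2=float("nan")),
    ]


@pytest.fixture(scope="session")
def full_catalog():
    return default_variant_catalog()


@pytest.fixture(scope="session")
def small_design(small_catalog):
    return SimulationDesign(
        n_subjects=400,
        catalog=small_catalog,
        cnv_loci=[CnvLocus("delA", "chr16", 21_500_000, 21_521_000, "DEL",
                           freq=0.169, effect=-1.0),
                  CnvLocus("dupB", "chr1", 16_800_000, 16_866_400, "DUP",
                           freq=0.05)],
    )


@pytest.fixture(scope="session")
def cohort_2348():
    """One default cohort at full size, shared across tests."""
    from snpcnv.simulate import simulate_cohort
    return simulate_cohort(default_design(), seed=20348)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
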