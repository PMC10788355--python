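import numpy as np
import pandas as pd
import pytest

from dartsex.panel import GenotypePanel, MarkerType, Sex, SexRegistry
from dartsex.simulate import SimConfig, emulate_study_scale, simulate_family


def make_panel(marker_type, calls, loci=None, individuals=None, meta=None):
    """Build a valid panel from a raw call matrix, synthesising metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_ind = calls.shape
    loci = loci or [f"L{i:03d}" for i in range(n_loci)]
    individuals = individuals or [f"S{j:02d}" for j in range(n_ind)]
    if meta is None:
        meta = pd.DataFrame(
            {
                "reproducibility": np.full(n_loci, 0.99),
                "avg_depth": np.full(n_loci, 20.0),
                "allele_balance": np.full(n_loci, 0.95),
                "call_rate": (calls != -1).mean(axis=1),
            },
            index=pd.Index(loci),
        )
        if MarkerType(marker_type) is MarkerType.PA:
            meta = meta.drop(columns=["allele_balance"])
    return GenotypePanel(
        marker_type=MarkerType(marker_type),
        loci=loci,
        individuals=individuals,
        calls=calls,
        locus_meta=meta,
    )


def make_registry(individuals, n_males):
    """First ``n_males`` individuals male, the rest female."""
    sex_of = {
        ind: (Sex.MALE if j < n_males else Sex.FEMALE)
        for j, ind in enumerate(individuals)
    }
    return SexRegistry(sex_of, list(individuals))


def random_panel(rng, marker_type, n_loci, n_ind, missing_rate=0.1):
    hi = 2 if MarkerType(marker_type) is MarkerType.SNP else 1
    calls = rng.integers(0, hi + 1, size=(n_loci, n_ind)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = -1
    return make_panel(marker_type, calls)


@pytest.fixture(scope="session")
def small_family():
    """A modest simulated full-sib family shared across tests (read-only)."""
    return simulate_family(
        SimConfig(n_snp_auto=400, n_pa_auto=400, n_snp_linked=10,
                  n_pa_linked=10, seed=7)
    )


@pytest.fixture(scope="session")
def study_family():
    """The full study-scale preset (20,129 SNP + 17,025 PA × 32), seed 1."""
    return emulate_study_scale(seed=1)
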