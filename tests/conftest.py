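import numpy as np
import pytest

from xskew.assay import AssayConfig, simulate_assays
from xskew.cr import call_assays
from xskew.pipeline import join_calls
from xskew.population import AgeBand, PopulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def simulate_calls_frame(pop_cfg: PopulationConfig, assay_cfg: AssayConfig):
    """Full simulate -> assay -> call chain as an analysis DataFrame."""
    subjects = simulate_cohort(pop_cfg)
    results = simulate_assays(subjects, assay_cfg)
    calls = call_assays(results)
    return join_calls(subjects, calls)


def single_band_cohort(n: int, age_lo: float, age_hi: float, seed: int, **kw) -> PopulationConfig:
    """Cohort config confined to one age band, fully informative by default."""
    kw.setdefault("heterozygosity", 1.0)
    return PopulationConfig(
        n_subjects=n,
        age_distribution=[(AgeBand(age_lo, age_hi), 1.0)],
        seed=seed,
        **kw,
    )
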