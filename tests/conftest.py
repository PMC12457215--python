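import numpy as np
import pytest

from doseqa.dose_model import DoseGrid, StructureMask
from doseqa.synthetic_cohort import PlanSimConfig, make_plan_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_grid():
    """5^3 uniform 10 Gy grid at 3 mm pitch."""
    return DoseGrid.from_arrays(np.full((5, 5, 5), 10.0), (0, 0, 0), (3, 3, 3))


@pytest.fixture
def random_pair(rng):
    """Paired 7^3 grids with ~1% relative disagreement on one geometry."""
    base = 40.0 + 20.0 * rng.random((7, 7, 7))
    ref = DoseGrid.from_arrays(base, (0, 0, 0), (2.5, 2.5, 2.5))
    eval_grid = DoseGrid.from_arrays(
        base * (1.0 + 0.01 * rng.standard_normal(base.shape)), (0, 0, 0), (2.5, 2.5, 2.5)
    )
    return ref, eval_grid


@pytest.fixture(scope="session")
def small_plan_pair():
    """A 24^3 synthetic plan pair with mild perturbations (session-cached)."""
    cfg = PlanSimConfig(
        shape=(24, 24, 24),
        target_radii_mm=(14, 12, 10),
        sys_mu=1.0,
        local_amp_pct=0.8,
        shift_mm=(0.4, 0.3, 0.2),
        mc_noise_rel_sd_pct=0.3,
    )
    return make_plan_pair(cfg, seed=42)
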