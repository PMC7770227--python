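import numpy as np
import pytest

from sdnmap.grid import Grid
from sdnmap.synthetic import CohortSpec, NetworkSpec, generate_cohort


def small_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A compact signal-bearing cohort for fast pipeline-level tests.

    24^3 grid, ~50 subjects, one strongly progressive network and one
    uniformly atrophying decoy; same structure as the default preset but
    sized so a full pipeline run takes a few seconds.
    """
    networks = [
        NetworkSpec(
            name="progressive",
            epicenter_ijk=(8, 12, 12),
            group_mean_rates={"HC": -0.002, "MCIs": -0.006, "MCIp": -0.030, "AD": -0.036},
            loading_sigma_vox=2.0,
            radius_vox=4.0,
            couples_cognition=True,
        ),
        NetworkSpec(
            name="stable",
            epicenter_ijk=(17, 12, 12),
            group_mean_rates={g: -0.010 for g in ("HC", "MCIs", "MCIp", "AD")},
            loading_sigma_vox=2.0,
            radius_vox=4.0,
        ),
    ]
    kwargs = dict(
        grid=Grid((24, 24, 24), 2.0),
        n_per_group={"HC": 16, "MCIs": 12, "MCIp": 8, "AD": 12},
        networks=networks,
        brain_radius_vox=10.0,
        cognitive_intercepts={"MMSE": -0.2},
        cognitive_coupling={"MMSE": 100.0},
        cognitive_noise_sd={"MMSE": 0.6},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    spec = small_cohort_spec(seed=7)
    return (spec, *generate_cohort(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
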