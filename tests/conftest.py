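import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from aslperf.quantify import AslSession, PerfusionMap  # noqa: E402


def make_map(values, affine=None, mask=None) -> PerfusionMap:
    """A PerfusionMap from a plain array (full mask, 3 mm grid by default)."""
    values = np.asarray(values, dtype=float)
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    if mask is None:
        mask = np.isfinite(values)
    return PerfusionMap(cbf=values, mask=mask, affine=affine, provenance={})


def make_session(series, tag_first=True, slice_duration_ms=0.0) -> AslSession:
    """A minimal session around a given 4D series (flat calibration scans)."""
    series = np.asarray(series, dtype=float)
    grid = series.shape[:3]
    csf = np.full(grid, 1000.0)
    ones = np.ones(grid)
    return AslSession(
        series=series,
        tr_ms=2500.0,
        ti1_ms=600.0,
        ti2_ms=1600.0,
        slice_duration_ms=slice_duration_ms,
        csf_scan=csf,
        csf_mask=ones > 0,
        min_contrast_reps=(ones.copy(), ones.copy()),
        brain_mask=ones > 0,
        affine=np.diag([3.0, 3.0, 3.0, 1.0]),
        tag_first=tag_first,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A small noiseless phantom cohort shared across tests."""
    from aslperf.phantom import make_phantom, noiseless_config

    cfg = noiseless_config(
        grid_shape=(16, 16, 8), n_pairs=4, n_per_group={"control": 2, "patient": 2}, seed=7
    )
    return cfg, make_phantom(cfg)
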