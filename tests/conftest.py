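import numpy as np
import pytest

from fwetract.synthetic import CohortConfig, generate_cohort, make_diffusion_scheme
from fwetract.tractometry import TractProfile


@pytest.fixture(scope="session")
def scheme():
    """The study acquisition: 55 directions at b = 2000 plus one b = 0."""
    return make_diffusion_scheme(55, 2000.0, 1, seed=0)


@pytest.fixture(scope="session")
def tiny_config():
    """Four-subject, four-tract cohort for fast structural tests."""
    return CohortConfig(
        n_per_group={"glioblastoma": 2, "astrocytoma": 1, "oligodendroglioma": 1},
        tracts=("ATR", "ARC", "pARC", "CGC"),
        n_streamlines=5,
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    records, manifest = generate_cohort(tiny_config)
    return records, manifest


def make_profile(tract="ILF", hemisphere="left", n_nodes=100, *,
                 metrics=None, combined=None, enhancing=None, necrotic=None,
                 edema=None):
    """Hand-built TractProfile with zero involvement unless specified."""
    def arr(x, fill=0.0):
        if x is None:
            return np.full(n_nodes, fill)
        return np.asarray(x, dtype=float)

    involvement = {
        "enhancing": arr(enhancing), "necrotic": arr(necrotic),
        "edema": arr(edema),
        "combined": arr(combined),
    }
    metric_arrays = {k: np.asarray(v, dtype=float)
                     for k, v in (metrics or {}).items()}
    return TractProfile(tract, hemisphere, n_nodes, metric_arrays, involvement)
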