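import numpy as np
import pytest

from xylemflow import piv as pivmod
from xylemflow import synthgen

#: image size used throughout the PIV tests: wide enough for the 128 px
#: initial window, tall enough for a resolved transverse profile
PIV_SHAPE = (64, 256)


@pytest.fixture(scope="session")
def poiseuille_truth():
    return synthgen.poiseuille_field(4.0, PIV_SHAPE)


@pytest.fixture(scope="session")
def poiseuille_mean_field(poiseuille_truth):
    """Ensemble-averaged PIV result on a seeded Poiseuille tracer ensemble."""
    fields = [
        pivmod.multipass_piv(synthgen.make_particle_image_pair(poiseuille_truth, seed=s))
        for s in range(20)
    ]
    return pivmod.ensemble_average(fields)


def run_uniform_ensemble(displacement: float, n_pairs: int, seed0: int = 0,
                         shape=PIV_SHAPE):
    """Mean measured u of each pair at a uniform true displacement."""
    fld_fn = synthgen.uniform_field(displacement, 0.0, shape)
    means = []
    for s in range(n_pairs):
        pair = synthgen.make_particle_image_pair(fld_fn, seed=seed0 + s)
        fld = pivmod.multipass_piv(pair)
        means.append(float(np.mean(fld.u[fld.valid])))
    return np.array(means)
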