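import numpy as np
import pytest

from octmel import PhantomSpec, generate_bscan, generate_cohort
from octmel.cli import run_experiment


@pytest.fixture(scope="session")
def clean_spec():
    """Speckle-free, texture-free reduced spec: exact Beer-Lambert decay."""
    return PhantomSpec.reduced(speckle_model="none", disarray_strength=0.0,
                               noise_floor=0.0)


@pytest.fixture(scope="session")
def speckled_spec():
    return PhantomSpec.reduced()


@pytest.fixture(scope="session")
def small_cohort():
    """2 induced + 2 control subjects, weeks 0..3, onset 2, 4 slices."""
    induced = PhantomSpec.reduced(n_slices=4, lesion_onset_week=2)
    control = PhantomSpec.reduced(n_slices=4)
    return generate_cohort(induced, control, 2, 2, [0, 1, 2, 3], master_seed=7)


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """One full experiment at the standard desk-scale study conditions.

    4 induced + 4 control subjects, 16 slices/volume, weeks 0-6, lesion onset
    at week 3; tiny_vgg trained with BCE and with BCE + relative loss on a
    subject-exclusive split.  Shared session-wide because training dominates
    the suite's runtime.
    """
    out_dir = tmp_path_factory.mktemp("e2e_run")
    return run_experiment({}, out_dir, seed=1)


@pytest.fixture(scope="session")
def trained_model(e2e):
    return e2e["models"]["cnn_bce_lossr"]
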