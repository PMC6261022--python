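import numpy as np
import pytest

from ostfmri.paradigm import ParadigmConfig, generate_paradigm, label_trials, simulate_behavior
from ostfmri.synth import NeuralSpec, SubjectDataset, synth_subject
from ostfmri.vwglm import VolumeWiseGLM

# A short-run configuration used throughout the unit tests: 80 trials /
# 20 stops over 160 volumes keeps a single vwGLM fit under a second
# while preserving every structural property of the full protocol.
SMALL = ParadigmConfig(n_trials=80, n_stop=20, n_volumes=160)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def labeled_paradigm():
    p = generate_paradigm(SMALL, seed=11)
    p = simulate_behavior(p, seed=12)
    return label_trials(p)


@pytest.fixture(scope="session")
def small_subject():
    return synth_subject("sub-small", config=SMALL, seed=21)


@pytest.fixture(scope="session")
def well_conditioned_subject():
    """Subject whose design stays numerically full rank at every fitted
    volume: iid motion of uniform scale and no censored volumes."""
    base = synth_subject("sub-cond", config=SMALL, seed=31)
    rng = np.random.default_rng(32)
    m6 = rng.normal(0.0, 0.02, size=(SMALL.n_volumes, 6))
    return SubjectDataset(
        base.subject_id,
        base.timecourses,
        base.tr,
        m6,
        np.zeros(SMALL.n_volumes),
        base.paradigm,
        base.group,
        base.sex,
    )


@pytest.fixture(scope="session")
def small_trajectory(small_subject):
    return VolumeWiseGLM(small_subject).fit()


@pytest.fixture(scope="session")
def noiseless_subject():
    """amp_sd = 0 and vanishing noise: betas are exactly identifiable."""
    spec = NeuralSpec(amp_sd=0.0, noise_sd=1e-10, ar1=0.0, drift_amp=0.0)
    return synth_subject("sub-clean", config=SMALL, spec=spec, seed=41)
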