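"""Synthetic per-subject IC timecourses, motion, and cohorts.

Stands in for preprocessed, ICA-reduced fMRI data: each subject is a
matrix of independent-component timecourses (volumes x components, percent
signal change) built from trial-evoked responses convolved with the
canonical HRF, plus AR(1) observation noise and low-frequency drift, with
head-motion parameter traces and framewise displacement alongside.

The key generative dial is the trial-by-trial response-amplitude standard
deviation (``amp_sd``): every trial's evoked amplitude is its trial-type
mean plus a zero-mean Gaussian deviation of that marginal SD.  The
deviations are serially correlated across trials (an AR(1) engagement
state per trial type and component, coefficient ``amp_rho``), modeling
slow attentional/engagement drift in responsiveness: a subject with a
large, slowly wandering amplitude state presents the GLM with a moving
target, so the beta trajectory keeps drifting and its SoAD decays slowly,
while a low-variance subject's betas settle quickly.  Setting
``amp_rho=0`` recovers independent trial-by-trial jitter, which perturbs
beta precision but leaves the decay *rate* nearly unchanged — serial
correlation is what converts amplitude variance into convergence speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf import cosine_drift_basis, event_regressor
from .paradigm import (
    Paradigm,
    ParadigmConfig,
    RaceModel,
    TRIAL_TYPES,
    generate_paradigm,
    label_trials,
    simulate_behavior,
)

__all__ = [
    "NeuralSpec",
    "SubjectDataset",
    "CohortSpec",
    "default_amp_mean",
    "synth_timecourses",
    "synth_motion",
    "synth_subject",
    "synth_cohort",
    "framewise_displacement",
]

ROTATION_RADIUS_MM = 50.0


def default_amp_mean(n_components: int = 22) -> np.ndarray:
    """Population-mean evoked amplitudes, [6 trial types x components], PSC.

    Deterministic structured pattern: each trial type loads on an
    overlapping subset of components with magnitudes in the 0.2-1.5 range,
    so types are correlated but distinguishable (as task conditions are in
    real IC timecourses).
    """
    rng = np.random.default_rng(20181126)  # fixed: part of the default spec
    shared = rng.normal(0.8, 0.2, size=n_components)
    amp = np.empty((len(TRIAL_TYPES), n_components))
    for i in range(len(TRIAL_TYPES)):
        amp[i] = shared + rng.normal(0.0, 0.35, size=n_components)
    amp[0] *= 0.5  # instruction block evokes a weaker response
    return amp


@dataclass
class NeuralSpec:
    """Generative parameters for one subject's IC timecourses.

    amp_mean : (6, n_components) evoked amplitude per trial type (rows in
        TRIAL_TYPES order), percent signal change.
    amp_sd : trial-by-trial amplitude deviation SD (same units); scalar or
        per-trial-type vector of length 6.  Controls beta-trajectory
        convergence speed (larger = slower) through the serially
        correlated engagement state.
    amp_rho : per-trial AR(1) coefficient of the amplitude state in
        [0, 1); 0 means independent jitter on every trial.
    noise_sd : marginal SD of the AR(1) observation noise.
    ar1 : lag-1 autocorrelation of the observation noise, in [0, 1).
    drift_amp : SD of random coefficients on the low-frequency cosine
        drift basis.
    motor_amp : (n_components,) amplitude of the button-press response.
    """

    n_components: int = 22
    amp_mean: np.ndarray | None = None
    amp_sd: float | np.ndarray = 0.6
    amp_rho: float = 0.97
    noise_sd: float = 1.0
    ar1: float = 0.3
    drift_amp: float = 0.5
    motor_amp: np.ndarray | float = 0.4
    drift_cutoff_hz: float = 1.0 / 128.0

    def __post_init__(self) -> None:
        if self.amp_mean is None:
            self.amp_mean = default_amp_mean(self.n_components)
        self.amp_mean = np.asarray(self.amp_mean, dtype=float)
        if self.amp_mean.shape != (len(TRIAL_TYPES), self.n_components):
            raise ValueError(
                f"amp_mean must be {(len(TRIAL_TYPES), self.n_components)}, "
                f"got {self.amp_mean.shape}"
            )
        sd = np.atleast_1d(np.asarray(self.amp_sd, dtype=float))
        if sd.size == 1:
            sd = np.full(len(TRIAL_TYPES), float(sd[0]))
        if sd.shape != (len(TRIAL_TYPES),):
            raise ValueError(
                f"amp_sd must be scalar or length {len(TRIAL_TYPES)}"
            )
        if np.any(sd < 0):
            raise ValueError("amp_sd must be >= 0")
        self.amp_sd = sd
        if not 0 <= self.amp_rho < 1:
            raise ValueError("amp_rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")
        if np.isscalar(self.motor_amp):
            self.motor_amp = np.full(self.n_components, float(self.motor_amp))
        else:
            self.motor_amp = np.asarray(self.motor_amp, dtype=float)


@dataclass
class SubjectDataset:
    """Everything the volume-wise GLM needs for one subject."""

    subject_id: str
    timecourses: np.ndarray  # (n_volumes, n_components)
    tr: float
    motion6: np.ndarray  # (n_volumes, 6)
    fd: np.ndarray  # (n_volumes,)
    paradigm: Paradigm
    group: str = "Con"  # CD | Con
    sex: str = "F"  # M | F

    def __post_init__(self) -> None:
        n = self.timecourses.shape[0]
        if self.motion6.shape != (n, 6):
            raise ValueError("motion6 must be (n_volumes, 6)")
        if self.fd.shape != (n,):
            raise ValueError("fd must have one entry per volume")
        if np.any(self.fd < 0):
            raise ValueError("fd must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.timecourses.shape[0]

    @property
    def n_components(self) -> int:
        return self.timecourses.shape[1]


def _task_signal(
    paradigm: Paradigm, spec: NeuralSpec, rng: np.random.Generator
) -> np.ndarray:
    """Noise-free evoked signal: per-trial amplitudes convolved with the HRF.

    The amplitude of each event is amp_mean[label] plus the current value
    of an AR(1) engagement state (one state per trial type x component,
    marginal SD amp_sd[label], per-trial coefficient amp_rho).  All states
    advance one AR step per task trial, so their correlation decays with
    trial lag regardless of which types occurred in between.
    """
    n_vol, tr = paradigm.n_volumes, paradigm.tr
    sig = np.zeros((n_vol, spec.n_components))
    type_index = {t: i for i, t in enumerate(TRIAL_TYPES)}
    sd = np.asarray(spec.amp_sd)[:, None]  # (6, 1)
    rho = spec.amp_rho
    states = rng.normal(0.0, 1.0, size=(len(TRIAL_TYPES), spec.n_components)) * sd
    onsets, amps = [], []
    for ev in paradigm.events:
        if ev.label not in type_index:
            continue
        j = type_index[ev.label]
        onsets.append(ev.onset)
        amps.append(spec.amp_mean[j] + states[j])
        innov = rng.normal(0.0, 1.0, size=states.shape) * sd
        states = rho * states + np.sqrt(1.0 - rho**2) * innov
    if onsets:
        resp = np.array([event_regressor([o], n_vol, tr).ravel() for o in onsets])
        sig += resp.T @ np.array(amps)
    # motor response at each button press
    press = [ev.onset + ev.rt / 1000.0 for ev in paradigm.events if ev.responded]
    if press:
        motor = event_regressor(np.array(press), n_vol, tr)
        sig += motor[:, None] * spec.motor_amp[None, :]
    return sig


def _ar1_noise(
    n_volumes: int, n_components: int, ar1: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - ar1**2)
    x = np.empty((n_volumes, n_components))
    x[0] = rng.normal(0.0, sd, size=n_components)
    eps = rng.normal(0.0, innov_sd, size=(n_volumes - 1, n_components))
    for t in range(1, n_volumes):
        x[t] = ar1 * x[t - 1] + eps[t - 1]
    return x


def synth_timecourses(
    paradigm: Paradigm, spec: NeuralSpec, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Synthesize (n_volumes, n_components) IC timecourses for a labeled paradigm.

    signal = per-trial jittered evoked response + motor response
             + cosine drift + AR(1) noise
    Deterministic given seed.
    """
    labeled = any(
        ev.is_task and ev.label in TRIAL_TYPES for ev in paradigm.events
    )
    if not labeled:
        raise ValueError("paradigm must be labeled before synthesis")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = _task_signal(paradigm, spec, rng)
    basis = cosine_drift_basis(paradigm.n_volumes, paradigm.tr, spec.drift_cutoff_hz)
    if basis.shape[1] and spec.drift_amp > 0:
        coef = rng.normal(0.0, spec.drift_amp, size=(basis.shape[1], spec.n_components))
        y += basis @ coef
    y += _ar1_noise(paradigm.n_volumes, spec.n_components, spec.ar1, spec.noise_sd, rng)
    return y


def framewise_displacement(motion6: np.ndarray, radius_mm: float = ROTATION_RADIUS_MM) -> np.ndarray:
    """FD as the sum of absolute backward differences of the 6 parameters.

    Columns 0-2 are translations (mm), columns 3-5 rotations (radians)
    converted to arc length on a ``radius_mm`` sphere.  FD at volume 0 is 0.
    """
    d = np.abs(np.diff(motion6, axis=0))
    d[:, 3:] *= radius_mm
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    return fd


def synth_motion(
    n_volumes: int,
    spike_prob: float = 0.02,
    seed: int | np.random.Generator = 0,
    walk_sd_mm: float = 0.01,
    spike_mm: tuple[float, float] = (0.6, 1.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk motion traces with occasional large spikes.

    Baseline motion is a per-parameter Gaussian random walk whose per-step
    FD stays well below the 0.5 censoring threshold.  With probability
    ``spike_prob`` per volume a persistent translation jump of
    ``spike_mm`` magnitude is added on one axis, pushing that volume's FD
    above threshold.  Returns (motion6, fd).
    """
    if n_volumes <= 0:
        raise ValueError("n_volumes must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    steps = rng.normal(0.0, walk_sd_mm, size=(n_volumes, 6))
    steps[:, 3:] /= ROTATION_RADIUS_MM  # rotations in radians, same FD scale
    steps[0] = 0.0
    spikes = rng.random(n_volumes) < spike_prob
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        mag = rng.uniform(*spike_mm) * rng.choice([-1.0, 1.0])
        steps[t, axis] += mag
    motion6 = np.cumsum(steps, axis=0)
    return motion6, framewise_displacement(motion6)


def synth_subject(
    subject_id: str,
    config: ParadigmConfig | None = None,
    race: RaceModel | None = None,
    spec: NeuralSpec | None = None,
    spike_prob: float = 0.02,
    group: str = "Con",
    sex: str = "F",
    seed: int | np.random.SeedSequence = 0,
) -> SubjectDataset:
    """Generate one subject end to end: paradigm, behavior, labels, data."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    s_par, s_beh, s_neu, s_mot = ss.spawn(4)
    config = config or ParadigmConfig()
    spec = spec or NeuralSpec()
    paradigm = generate_paradigm(config, np.random.default_rng(s_par))
    paradigm = simulate_behavior(
        paradigm, race or RaceModel(), np.random.default_rng(s_beh),
        ssd_init=config.ssd_init_ms, ssd_step=config.ssd_step_ms,
    )
    paradigm = label_trials(paradigm)
    y = synth_timecourses(paradigm, spec, np.random.default_rng(s_neu))
    motion6, fd = synth_motion(config.n_volumes, spike_prob, np.random.default_rng(s_mot))
    return SubjectDataset(
        subject_id=subject_id,
        timecourses=y,
        tr=config.tr_s,
        motion6=motion6,
        fd=fd,
        paradigm=paradigm,
        group=group,
        sex=sex,
    )


@dataclass
class CohortSpec:
    """Population-level generative parameters for a two-group cohort.

    ``group_effect`` is an amplitude offset (PSC) added to the cocaine-
    dependent (CD) group's mean response on ``effect_cells`` — a list of
    (trial_type, component) pairs.  ``subject_sd`` is between-subject
    jitter on every amplitude cell.  Per-subject amp_sd is log-normal so
    convergence speed varies realistically across the cohort.  Male
    fractions default to the study composition (30/40 CD, 14/27 Con).
    """

    n_cd: int = 40
    n_con: int = 27
    group_effect: float = 0.5
    effect_cells: list[tuple[str, int]] | None = None
    subject_sd: float = 0.15
    amp_sd_log_mu: float = float(np.log(0.6))
    amp_sd_log_sigma: float = 0.4
    #: optional per-trial-type multiplier on each subject's amp_sd,
    #: e.g. {"GfSS": 4.0} inflates GfSS trial-by-trial variance cohort-wide
    type_amp_sd_scale: dict[str, float] | None = None
    male_frac_cd: float = 30.0 / 40.0
    male_frac_con: float = 14.0 / 27.0
    n_components: int = 22
    noise_sd: float = 1.0
    ar1: float = 0.3
    drift_amp: float = 0.5
    spike_prob: float = 0.02

    def resolved_effect_cells(self) -> list[tuple[str, int]]:
        if self.effect_cells is not None:
            return self.effect_cells
        # stop-related responses on the first 8 components
        return [(t, c) for t in ("SS", "FS") for c in range(min(8, self.n_components))]


def synth_cohort(
    cohort: CohortSpec | None = None,
    config: ParadigmConfig | None = None,
    race: RaceModel | None = None,
    seed: int = 0,
) -> list[SubjectDataset]:
    """Generate a CD/Con cohort of SubjectDatasets.

    Per-subject seeds are spawned from a single SeedSequence so each
    subject's stream is independent of cohort size and order.
    """
    cohort = cohort or CohortSpec()
    config = config or ParadigmConfig()
    root = np.random.SeedSequence(seed)
    pop_rng = np.random.default_rng(root.spawn(1)[0])
    n_total = cohort.n_cd + cohort.n_con
    subject_seeds = root.spawn(n_total)

    pop_mean = default_amp_mean(cohort.n_components)
    type_index = {t: i for i, t in enumerate(TRIAL_TYPES)}
    effect = np.zeros_like(pop_mean)
    for t, c in cohort.resolved_effect_cells():
        effect[type_index[t], c] = cohort.group_effect

    def n_males(n: int, frac: float) -> int:
        return int(round(n * frac))

    sexes = (
        ["M"] * n_males(cohort.n_cd, cohort.male_frac_cd)
        + ["F"] * (cohort.n_cd - n_males(cohort.n_cd, cohort.male_frac_cd))
        + ["M"] * n_males(cohort.n_con, cohort.male_frac_con)
        + ["F"] * (cohort.n_con - n_males(cohort.n_con, cohort.male_frac_con))
    )
    groups = ["CD"] * cohort.n_cd + ["Con"] * cohort.n_con

    subjects = []
    for i in range(n_total):
        amp = pop_mean + (effect if groups[i] == "CD" else 0.0)
        amp = amp + pop_rng.normal(0.0, cohort.subject_sd, size=amp.shape)
        amp_sd: float | np.ndarray = float(
            pop_rng.lognormal(cohort.amp_sd_log_mu, cohort.amp_sd_log_sigma)
        )
        if cohort.type_amp_sd_scale:
            scale = np.ones(len(TRIAL_TYPES))
            for t, s in cohort.type_amp_sd_scale.items():
                scale[type_index[t]] = s
            amp_sd = amp_sd * scale
        spec = NeuralSpec(
            n_components=cohort.n_components,
            amp_mean=amp,
            amp_sd=amp_sd,
            noise_sd=cohort.noise_sd,
            ar1=cohort.ar1,
            drift_amp=cohort.drift_amp,
        )
        subjects.append(
            synth_subject(
                subject_id=f"sub-{i + 1:03d}",
                config=config,
                race=race,
                spec=spec,
                spike_prob=cohort.spike_prob,
                group=groups[i],
                sex=sexes[i],
                seed=subject_seeds[i],
            )
        )
    return subjects
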