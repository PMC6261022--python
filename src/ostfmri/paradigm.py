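"""Stop-signal task paradigm: trial sequences, the adaptive SSD staircase,
and a horse-race behavioral simulator.

The stop-signal task (SST) presents a stream of go stimuli; on a subset of
trials a stop signal follows the go stimulus after a stop-signal delay
(SSD).  The SSD is adapted by a one-up/one-down staircase (+50 ms after a
successful stop, -50 ms after a failed stop) so that stopping succeeds on
roughly half the stop trials.  Behavior is modeled as an independent horse
race between a go process with ex-Gaussian finishing times and a stop
process of fixed latency (the stop-signal reaction time, SSRT): the stop
wins, and the response is inhibited, iff SSD + SSRT precedes the go
process's finishing time.

Trial types follow the convention used for GLM modeling of the SST:
stop trials are labeled by their own outcome (SS = successful stop,
FS = failed stop) and go trials by their immediately preceding task trial
(GG = go following go, GfSS = go following successful stop, GfFS = go
following failed stop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrialEvent",
    "Paradigm",
    "RaceModel",
    "ParadigmConfig",
    "generate_paradigm",
    "update_ssd",
    "simulate_behavior",
    "label_trials",
    "reconstruct_ssd_sequence",
    "stop_success_rate",
]

GO_LABELS = ("GG", "GfSS", "GfFS")
STOP_LABELS = ("SS", "FS")
TASK_LABELS = GO_LABELS + STOP_LABELS
#: Regressor order used throughout the GLM machinery.
TRIAL_TYPES = ("instruction",) + TASK_LABELS

SSD_STEP_MS = 50.0
SSD_INIT_MS = 250.0


class InvalidConfigurationError(ValueError):
    pass


class UnlabeledBehaviorError(RuntimeError):
    """Raised when labels are requested before behavior has been simulated."""


@dataclass
class TrialEvent:
    """One paradigm event.

    ``onset`` is in seconds from run start; ``ssd`` and ``rt`` are in
    milliseconds.  ``ssd`` is present only on stop trials, ``rt`` only when
    ``responded`` is true.
    """

    index: int
    onset: float
    base_type: str  # go | stop | instruction | rest
    duration: float = 0.0
    ssd: float | None = None
    responded: bool = False
    rt: float | None = None
    label: str = "none"

    @property
    def is_task(self) -> bool:
        return self.base_type in ("go", "stop")


@dataclass
class Paradigm:
    """An ordered stop-signal-task event sequence plus scan geometry."""

    events: list[TrialEvent]
    tr: float = 2.0
    n_volumes: int = 502
    iti: float = 2000.0
    rest_blocks: list[tuple[float, float]] = field(default_factory=list)

    @property
    def task_events(self) -> list[TrialEvent]:
        return [e for e in self.events if e.is_task]

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def copy(self) -> "Paradigm":
        return Paradigm(
            events=[replace(e) for e in self.events],
            tr=self.tr,
            n_volumes=self.n_volumes,
            iti=self.iti,
            rest_blocks=list(self.rest_blocks),
        )

    def validate(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b >= a for a, b in zip(onsets[1:], onsets)):
            raise ValueError("event onsets must be strictly increasing")
        horizon = self.duration
        late = [e for e in self.events if e.onset >= horizon]
        if late:
            raise ValueError(
                f"event at {late[0].onset:.1f}s lies beyond scan end {horizon:.1f}s"
            )


@dataclass(frozen=True)
class RaceModel:
    """Independent horse-race behavioral model.

    Go finishing times are ex-Gaussian: Normal(go_rt_mu, go_rt_sigma) plus
    an Exponential(go_rt_tau) tail, all in milliseconds.  ``ssrt`` is the
    latency of the stop process.  ``omission_rate`` is the probability that
    the go process never finishes on a trial (no response).
    """

    go_rt_mu: float = 450.0
    go_rt_sigma: float = 80.0
    go_rt_tau: float = 60.0
    ssrt: float = 250.0
    omission_rate: float = 0.02

    def __post_init__(self) -> None:
        vals = (self.go_rt_mu, self.go_rt_sigma, self.go_rt_tau, self.ssrt)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("race-model parameters must be finite")
        if self.go_rt_sigma <= 0:
            raise ValueError("go_rt_sigma must be > 0")
        if self.ssrt <= 0:
            raise ValueError("ssrt must be > 0")
        if not 0 <= self.omission_rate < 1:
            raise ValueError("omission_rate must lie in [0, 1)")

    def sample_go_finish(self, rng: np.random.Generator) -> float:
        return float(
            rng.normal(self.go_rt_mu, self.go_rt_sigma)
            + rng.exponential(self.go_rt_tau)
        )


@dataclass(frozen=True)
class ParadigmConfig:
    """Trial counts and timing of the default performance-adjusted SST.

    The default run has 300 go/stop trials of which 75 are stop trials, a
    fixed 2,000 ms inter-trial interval, three 20 s rest blocks, and one
    instruction block at run start.  ``stim_ms`` is the stimulus window
    preceding each ITI; together they set the per-trial period.  Any scan
    time beyond the last event is padding at the end of the run.
    """

    n_trials: int = 300
    n_stop: int = 75
    iti_ms: float = 2000.0
    stim_ms: float = 1000.0
    ssd_init_ms: float = SSD_INIT_MS
    ssd_step_ms: float = SSD_STEP_MS
    n_rest_blocks: int = 3
    rest_duration_s: float = 20.0
    instruction_duration_s: float = 4.0
    tr_s: float = 2.0
    n_volumes: int = 502

    def __post_init__(self) -> None:
        if self.n_stop > self.n_trials:
            raise InvalidConfigurationError(
                f"stop_count {self.n_stop} exceeds trial_count {self.n_trials}"
            )
        if self.n_trials < 0 or self.n_stop < 0:
            raise InvalidConfigurationError("trial counts must be non-negative")
        if self.n_stop > (self.n_trials + 1) // 2:
            raise InvalidConfigurationError(
                "cannot place stop trials without consecutive pairs: "
                f"{self.n_stop} > ceil({self.n_trials}/2)"
            )


def _draw_stop_positions(
    n_trials: int, n_stop: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw of stop-trial slots with no two consecutive.

    Uses the standard bijection between size-k subsets of {0..n-k} and
    non-adjacent size-k subsets of {0..n-1} (add i to the i-th order
    statistic), which makes the draw uniform over admissible placements.
    """
    if n_stop == 0:
        return np.empty(0, dtype=int)
    base = rng.choice(n_trials - n_stop + 1, size=n_stop, replace=False)
    base.sort()
    return base + np.arange(n_stop)


def generate_paradigm(
    config: ParadigmConfig | None = None, seed: int | None = 0
) -> Paradigm:
    """Generate an unperformed stop-signal paradigm.

    Stop positions are drawn uniformly among trial slots subject to no two
    consecutive stop trials; SSDs are left unset until behavior is
    simulated.  Deterministic given ``seed``.
    """
    config = config or ParadigmConfig()
    rng = np.random.default_rng(seed)
    stop_slots = set(_draw_stop_positions(config.n_trials, config.n_stop, rng).tolist())

    events: list[TrialEvent] = []
    cursor = 0.0
    idx = 0
    if config.instruction_duration_s > 0:
        events.append(
            TrialEvent(
                index=idx,
                onset=cursor,
                base_type="instruction",
                duration=config.instruction_duration_s,
                label="instruction",
            )
        )
        idx += 1
        cursor += config.instruction_duration_s

    # rest blocks evenly interleaved among the trial sequence
    rest_after = set()
    if config.n_rest_blocks > 0 and config.n_trials > 0:
        step = config.n_trials / (config.n_rest_blocks + 1)
        rest_after = {int(round(step * (j + 1))) - 1 for j in range(config.n_rest_blocks)}

    rest_blocks: list[tuple[float, float]] = []
    trial_period_s = (config.stim_ms + config.iti_ms) / 1000.0
    for i in range(config.n_trials):
        events.append(
            TrialEvent(
                index=idx,
                onset=cursor,
                base_type="stop" if i in stop_slots else "go",
                duration=config.stim_ms / 1000.0,
            )
        )
        idx += 1
        cursor += trial_period_s
        if i in rest_after:
            events.append(
                TrialEvent(
                    index=idx,
                    onset=cursor,
                    base_type="rest",
                    duration=config.rest_duration_s,
                )
            )
            idx += 1
            rest_blocks.append((cursor, config.rest_duration_s))
            cursor += config.rest_duration_s

    paradigm = Paradigm(
        events=events,
        tr=config.tr_s,
        n_volumes=config.n_volumes,
        iti=config.iti_ms,
        rest_blocks=rest_blocks,
    )
    paradigm.validate()
    return paradigm


def update_ssd(ssd: float, stop_outcome: str, step: float = SSD_STEP_MS,
               floor: float = 0.0) -> float:
    """One-up/one-down staircase step.

    +``step`` ms after a successful stop, -``step`` ms (floored at 0) after
    a failed stop.
    """
    if ssd < 0:
        raise ValueError(f"invalid staircase state: ssd={ssd}")
    if stop_outcome == "success":
        return ssd + step
    if stop_outcome == "failure":
        return max(ssd - step, floor)
    raise ValueError(f"unknown stop outcome {stop_outcome!r}")


def simulate_behavior(
    paradigm: Paradigm,
    model: RaceModel | None = None,
    seed: int | None = 0,
    ssd_init: float = SSD_INIT_MS,
    ssd_step: float = SSD_STEP_MS,
) -> Paradigm:
    """Run the horse race over every task trial and fill in responses.

    Go trials respond with probability 1 - omission_rate with an
    ex-Gaussian RT.  On stop trials the stop process (launched at the
    current SSD) wins iff ssd + ssrt < the sampled go finishing time; the
    SSD staircase is updated after every stop trial.  Returns a new
    Paradigm; deterministic given ``seed``.
    """
    model = model or RaceModel()
    rng = np.random.default_rng(seed)
    out = paradigm.copy()
    ssd = float(ssd_init)
    for ev in out.events:
        if not ev.is_task:
            continue
        go_finish = model.sample_go_finish(rng)
        omitted = rng.random() < model.omission_rate
        if ev.base_type == "go":
            if omitted:
                ev.responded, ev.rt = False, None
            else:
                ev.responded, ev.rt = True, go_finish
        else:  # stop trial: race
            ev.ssd = ssd
            stop_wins = omitted or (ssd + model.ssrt < go_finish)
            if stop_wins:
                ev.responded, ev.rt = False, None
                ssd = update_ssd(ssd, "success", step=ssd_step)
            else:
                ev.responded, ev.rt = True, go_finish
                ssd = update_ssd(ssd, "failure", step=ssd_step)
    return out


def label_trials(paradigm: Paradigm) -> Paradigm:
    """Assign SST trial-type labels.

    Stop trials are labeled from their own outcome (SS/FS); go trials from
    the immediately preceding task trial (GG/GfSS/GfFS).  The first task
    trial and go trials following instruction or rest default to GG.
    """
    out = paradigm.copy()
    for ev in out.events:
        if ev.base_type == "stop" and ev.ssd is None:
            raise UnlabeledBehaviorError(
                "behavior has not been simulated (stop trial without ssd)"
            )
    prev_label: str | None = None
    for ev in out.events:
        if ev.base_type == "instruction":
            ev.label = "instruction"
            continue
        if ev.base_type == "rest":
            ev.label = "none"
            prev_label = None  # go after rest defaults to GG
            continue
        if ev.base_type == "stop":
            ev.label = "FS" if ev.responded else "SS"
        else:
            if prev_label == "SS":
                ev.label = "GfSS"
            elif prev_label == "FS":
                ev.label = "GfFS"
            else:
                ev.label = "GG"
        prev_label = ev.label
    return out


def reconstruct_ssd_sequence(
    labels: list[str], ssd_init: float = SSD_INIT_MS, ssd_step: float = SSD_STEP_MS
) -> list[float]:
    """SSD sequence implied by an SS/FS label sequence and the initial SSD.

    The staircase is deterministic given outcomes, so the stored per-trial
    SSDs must round-trip through this reconstruction.
    """
    ssds = []
    ssd = float(ssd_init)
    for lab in labels:
        if lab not in STOP_LABELS:
            raise ValueError(f"expected SS/FS labels, got {lab!r}")
        ssds.append(ssd)
        ssd = update_ssd(ssd, "success" if lab == "SS" else "failure", step=ssd_step)
    return ssds


def stop_success_rate(paradigm: Paradigm) -> float:
    """Fraction of stop trials successfully inhibited."""
    stops = [e for e in paradigm.task_events if e.base_type == "stop"]
    if not stops:
        raise ValueError("paradigm has no stop trials")
    return sum(not e.responded for e in stops) / len(stops)
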