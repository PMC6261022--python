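"""Exponential-decay convergence modeling and optimal stopping times.

The convergence of a subject's volume-wise GLM beta trajectory is tracked
by the sum of absolute differences (SoAD) of beta weights between
consecutive volumes, summed over all usable components.  The SoAD series
is modeled as single exponential decay

    N(t) = N0 * exp(-lambda * t),

fit by regressing ln N(t) on the volume index t (the log transform makes
the model linear) with robust bisquare regression, so occasional large
SoAD excursions do not dominate the slope.  The decay constant converts
to a half-life t_half = ln(2)/lambda, and the optimal stopping time (OST)
at k half-lives is the volume at which SoAD has fallen by
100*(1 - 2^-k) percent — 50, 75, 87.5, 93.75 % for k = 1..4 — capped at
the last acquired volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .vwglm import BetaTrajectory, InsufficientDataError

__all__ = [
    "SoADSeries",
    "DecayFit",
    "OSTEstimate",
    "SoADDecay",
    "soad",
    "robust_linfit",
    "fit_decay",
    "ost",
    "combined_ost",
    "decay_fraction",
    "ost_quartiles",
    "SingularDesignError",
]

TASK_TRIAL_TYPES = ("GfSS", "GfFS", "SS", "FS")
BISQUARE_TUNE = 4.685
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50


class SingularDesignError(ValueError):
    pass


@dataclass
class SoADSeries:
    """Per-volume SoAD of one subject x trial type.

    ``t_values`` are the 1-based volume indices t_start+1..T; ``soad[i]``
    is sum_c |beta_t(c) - beta_{t-1}(c)| at t = t_values[i].
    """

    subject_id: str
    trial_type: str
    t_values: np.ndarray
    soad: np.ndarray

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values)
        self.soad = np.asarray(self.soad, dtype=float)
        if self.t_values.shape != self.soad.shape:
            raise ValueError("t_values and soad must have equal length")
        if np.any(self.soad < 0):
            raise ValueError("soad values must be non-negative")


def soad(trajectory: BetaTrajectory, trial_type: str) -> SoADSeries:
    """SoAD series of one trial type, summed over all components."""
    if trajectory.betas.shape[0] < 2:
        raise InsufficientDataError(
            "beta trajectory must span at least 2 volumes"
        )
    j = trajectory.trial_types.index(trial_type)
    b = trajectory.betas[:, j, :]  # (n_t, n_components)
    values = np.abs(np.diff(b, axis=0)).sum(axis=1)
    return SoADSeries(
        subject_id=trajectory.subject_id,
        trial_type=trial_type,
        t_values=trajectory.volumes[1:],
        soad=values,
    )


def _madsigma(residuals: np.ndarray, p: int) -> float:
    """Robust scale: median of the largest n-p+1 |residuals| over 0.6745."""
    rs = np.sort(np.abs(residuals))
    return float(np.median(rs[max(0, p - 1):]) / 0.6745)


def robust_linfit(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, np.ndarray, bool]:
    """Robust simple linear regression by IRLS with Tukey bisquare weights.

    Follows the commonly documented bisquare defaults: tuning constant
    4.685, scale MAD/0.6745 computed on leverage-adjusted residuals
    r / sqrt(1 - h), iterated until the relative coefficient change drops
    below 1e-8 or 50 iterations.  Returns (slope, intercept, weights,
    converged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise SingularDesignError("all x values identical")

    X = np.column_stack([np.ones(n), x])
    p = 2
    # hat diagonal for the leverage adjustment
    Q, _ = np.linalg.qr(X)
    h = np.minimum((Q**2).sum(axis=1), 0.9999)
    adj = 1.0 / np.sqrt(1.0 - h)
    tiny_s = 1e-6 * float(np.std(y)) or 1.0

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(n)
    converged = False
    for _ in range(IRLS_MAX_ITER):
        r = (y - X @ beta) * adj
        s = max(_madsigma(r, p), tiny_s)
        u = r / (BISQUARE_TUNE * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        delta = np.max(np.abs(beta_new - beta))
        scale = max(np.max(np.abs(beta_new)), np.max(np.abs(beta)), 1.0)
        beta = beta_new
        if delta <= IRLS_TOL * scale:
            converged = True
            break
    return float(beta[1]), float(beta[0]), w, converged


@dataclass
class DecayFit:
    """Exponential-decay fit of one SoAD series.

    valid requires lambda > 0 (a decaying series); otherwise t_half is
    undefined and downstream stopping times fall back to the last volume.
    """

    subject_id: str
    trial_type: str
    n0: float
    lam: float
    t_half: float  # nan when invalid
    n_points_used: int
    n_excluded: int
    robust_weights_converged: bool
    valid: bool
    method: str = "robust"

    def predict(self, t: np.ndarray | float) -> np.ndarray:
        """Fitted SoAD value N0 * exp(-lambda t)."""
        return self.n0 * np.exp(-self.lam * np.asarray(t, dtype=float))

    def summary(self) -> str:
        lines = [
            "Exponential decay of SoAD (log-linear "
            f"{'robust bisquare' if self.method == 'robust' else 'OLS'} fit)",
            f"  subject:    {self.subject_id}",
            f"  trial type: {self.trial_type}",
            f"  N0:         {self.n0:.6g}",
            f"  lambda:     {self.lam:.6g} per volume",
            f"  t_half:     {self.t_half:.4g} volumes"
            if self.valid
            else "  t_half:     undefined (lambda <= 0: no decay)",
            f"  points:     {self.n_points_used} used, "
            f"{self.n_excluded} non-positive excluded",
            f"  IRLS converged: {self.robust_weights_converged}",
        ]
        return "\n".join(lines)


class SoADDecay:
    """Model object: exponential decay of a SoAD series.

    ``fit()`` regresses ln(SoAD) on the volume index over the strictly
    positive SoAD values (non-positive values cannot be log-transformed
    and are excluded, with the count recorded) and returns a DecayFit.
    """

    def __init__(self, series: SoADSeries, robust: bool = True) -> None:
        self.series = series
        self.robust = robust

    def fit(self) -> DecayFit:
        pos = self.series.soad > 0
        n_excluded = int((~pos).sum())
        t = np.asarray(self.series.t_values, dtype=float)[pos]
        y = np.log(self.series.soad[pos])
        if t.size < 3:
            raise InsufficientDataError(
                f"need >= 3 strictly positive SoAD values, got {t.size}"
            )
        if self.robust:
            slope, intercept, _, converged = robust_linfit(t, y)
        else:
            X = np.column_stack([np.ones(t.size), t])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            intercept, slope = float(beta[0]), float(beta[1])
            converged = True
        lam = -slope
        valid = lam > 0
        return DecayFit(
            subject_id=self.series.subject_id,
            trial_type=self.series.trial_type,
            n0=math.exp(intercept),
            lam=lam,
            t_half=math.log(2) / lam if valid else math.nan,
            n_points_used=int(t.size),
            n_excluded=n_excluded,
            robust_weights_converged=converged,
            valid=valid,
            method="robust" if self.robust else "ols",
        )


def fit_decay(series: SoADSeries, robust: bool = True) -> DecayFit:
    """Functional wrapper: ``SoADDecay(series, robust).fit()``."""
    return SoADDecay(series, robust=robust).fit()


@dataclass
class OSTEstimate:
    """Stopping volume at k half-lives for one subject x trial type."""

    subject_id: str
    trial_type: str
    k: float
    stop_volume: int
    clipped: bool
    valid_fit: bool = True


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def ost(
    fit: DecayFit,
    k: float,
    t_start: int,
    T: int,
    anchor: str = "t_start",
) -> OSTEstimate:
    """Optimal stopping volume at ``k`` half-lives.

    The decay clock anchors at the first fitted volume by default (no
    SoAD exists earlier); ``anchor="zero"`` counts half-lives from volume
    0 instead.  Estimates beyond the last acquired volume T are clipped
    to T (the last volume's betas stand in), as are invalid fits
    (lambda <= 0, no measurable decay).
    """
    if k not in (1, 2, 3, 4):
        warnings.warn(
            f"k={k} outside the conventional 1-4 half-life range",
            stacklevel=2,
        )
    if anchor not in ("t_start", "zero"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if not fit.valid:
        return OSTEstimate(
            fit.subject_id, fit.trial_type, k, T, clipped=True, valid_fit=False
        )
    base = t_start if anchor == "t_start" else 0
    raw = base + _round_half_up(k * fit.t_half)
    if raw > T:
        return OSTEstimate(fit.subject_id, fit.trial_type, k, T, clipped=True)
    return OSTEstimate(fit.subject_id, fit.trial_type, k, max(raw, 1), clipped=False)


def combined_ost(per_type: dict[str, OSTEstimate] | list[OSTEstimate]) -> int:
    """The subject's overall OST: the largest stop volume across the four
    task trial types (all of GfSS, GfFS, SS, FS must be present)."""
    if isinstance(per_type, dict):
        estimates = per_type
    else:
        estimates = {e.trial_type: e for e in per_type}
    missing = [t for t in TASK_TRIAL_TYPES if t not in estimates]
    if missing:
        raise ValueError(f"incomplete trial-type set, missing {missing}")
    return max(estimates[t].stop_volume for t in TASK_TRIAL_TYPES)


def decay_fraction(k: float) -> float:
    """Percent decline of the decaying quantity after ``k`` half-lives:
    100 * (1 - 2^-k); 50/75/87.5/93.75 % for k = 1..4."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 100.0 * (1.0 - 2.0 ** (-k))


def ost_quartiles(values: np.ndarray) -> dict[str, float]:
    """Box-plot statistics of a set of stopping volumes: median, quartiles,
    and the count of points beyond 1.5 IQR whiskers."""
    v = np.asarray(values, dtype=float)
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    outliers = int(np.sum((v < q25 - 1.5 * iqr) | (v > q75 + 1.5 * iqr)))
    return {
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "iqr": float(iqr),
        "n_outliers": outliers,
        "n": int(v.size),
    }
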