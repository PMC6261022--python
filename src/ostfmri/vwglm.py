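"""Volume-wise general linear regression (vwGLR).

The GLM is refit on the first t volumes for t = t_start..T, and the six
trial-type beta weights are saved at every t, producing a per-subject,
per-component beta trajectory whose convergence the decay analysis
models.  The design holds HRF-convolved trial-type regressors
(instruction, GG, GfSS, GfFS, SS, FS), an HRF-convolved motor-response
regressor at every button press, 24 motion regressors (raw, raw^2,
backward difference, difference^2), an intercept, and low-frequency
cosine drift columns.  Volumes with framewise displacement above
threshold are censored (deleted) from every fit.

Estimation is ordinary least squares solved minimum-norm via the
pseudoinverse; an optional AR(1) prewhitening flag is provided, but no
equivalence with REML-based software is claimed.  The default engine
refits from scratch at every t; a QR row-append fast path (square-root
recursive least squares) is also available and agrees with the from-
scratch solve wherever the per-t design is numerically full rank.  Early
fits (tens of rows against ~47 regressors) can be genuinely
rank-deficient; those volumes are solved minimum-norm and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hrf import cosine_drift_basis, event_regressor
from .paradigm import Paradigm, TRIAL_TYPES
from .synth import SubjectDataset

__all__ = [
    "DesignMatrix",
    "BetaTrajectory",
    "VolumeWiseGLM",
    "build_design",
    "censor_mask",
    "first_valid_volume",
    "fit_glm",
    "run_vwglm",
    "InsufficientDataError",
]

BURN_IN = 50  # 49-volume burn-in: first fitted volume is the 50th
FD_THRESHOLD = 0.5
_SUPPORT_TOL = 1e-8


class InsufficientDataError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Named design matrix (volumes x regressors)."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("name count must match column count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("column names must be unique")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    #: regressors whose support gates the start of the volume-wise loop
    @property
    def support_columns(self) -> list[str]:
        return list(TRIAL_TYPES) + ["motor"]


def _motion24(motion6: np.ndarray) -> np.ndarray:
    """Raw, raw^2, backward difference, difference^2 (first diff row = 0)."""
    diff = np.vstack([np.zeros((1, 6)), np.diff(motion6, axis=0)])
    return np.hstack([motion6, motion6**2, diff, diff**2])


def build_design(
    paradigm: Paradigm,
    motion6: np.ndarray,
    tr: float | None = None,
    n_volumes: int | None = None,
    drift_cutoff_hz: float = 1.0 / 128.0,
) -> DesignMatrix:
    """Assemble the vwGLR design for one subject.

    Trial-type and motor columns are impulse trains convolved with the
    canonical HRF, sampled at volume acquisition times; motion columns are
    the 24-parameter expansion of the 6 realignment parameters.
    """
    tr = paradigm.tr if tr is None else tr
    n_volumes = paradigm.n_volumes if n_volumes is None else n_volumes
    if motion6.shape[0] != n_volumes:
        raise ValueError(
            f"motion6 has {motion6.shape[0]} rows for {n_volumes} volumes"
        )
    horizon = n_volumes * tr
    for ev in paradigm.events:
        if ev.onset >= horizon:
            raise ValueError(
                f"event at {ev.onset:.1f}s is beyond scan end {horizon:.1f}s"
            )

    cols, names = [], []
    for label in TRIAL_TYPES:
        onsets = np.array(
            [ev.onset for ev in paradigm.events if ev.label == label]
        )
        cols.append(event_regressor(onsets, n_volumes, tr))
        names.append(label)
    press = np.array(
        [ev.onset + ev.rt / 1000.0 for ev in paradigm.events if ev.responded]
    )
    cols.append(event_regressor(press, n_volumes, tr))
    names.append("motor")

    m24 = _motion24(np.asarray(motion6, dtype=float))
    blocks = ("raw", "sq", "diff", "diffsq")
    for b, block in enumerate(blocks):
        for p in range(6):
            cols.append(m24[:, 6 * b + p])
            names.append(f"mot{p + 1}_{block}")

    cols.append(np.ones(n_volumes))
    names.append("intercept")
    drift = cosine_drift_basis(n_volumes, tr, drift_cutoff_hz)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_{k + 1}")

    return DesignMatrix(np.column_stack(cols), names)


def censor_mask(fd: np.ndarray, threshold: float = FD_THRESHOLD) -> np.ndarray:
    """Keep-mask: True where FD <= threshold (strictly greater is dropped)."""
    fd = np.asarray(fd, dtype=float)
    if not np.all(np.isfinite(fd)) or np.any(fd < 0):
        raise ValueError("fd must be finite and non-negative")
    return fd <= threshold


def first_valid_volume(design: DesignMatrix, burn_in: int = BURN_IN) -> int:
    """First volume (1-based) at which the volume-wise loop may start.

    max(burn_in, smallest t such that every trial-type regressor and the
    motor regressor has nonzero support within volumes 1..t).  If some
    gating regressor never has support, returns T+1 (no-convergence
    sentinel; the subject is flagged rather than fit).
    """
    T = design.n_volumes
    t_req = burn_in
    for name in design.support_columns:
        col = np.abs(design.column(name)) > _SUPPORT_TOL
        nz = np.flatnonzero(col)
        if nz.size == 0:
            return T + 1
        t_req = max(t_req, int(nz[0]) + 1)  # 1-based
    return t_req


def fit_glm(
    Y: np.ndarray, X: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, bool]:
    """Minimum-norm OLS of each column of Y on X over unmasked rows.

    Returns (betas [n_regressors x n_components], rank_deficient flag).
    Censored rows are deleted before solving.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and X.shape[0] != 1:
        Y = Y.T
    if mask is not None:
        X, Y = X[mask], Y[mask]
    if X.shape[0] < 2:
        raise InsufficientDataError(
            f"only {X.shape[0]} uncensored volumes available"
        )
    betas, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    return betas, rank < X.shape[1]


@dataclass
class BetaTrajectory:
    """vwGLR results: trial-type beta weights saved at every fitted volume.

    ``betas[i, j, c]`` is the beta of trial type ``trial_types[j]`` for
    component c from the GLM fit on volumes 1..(t_start + i).  Volumes are
    1-based throughout.
    """

    subject_id: str
    t_start: int
    betas: np.ndarray  # (n_t, 6, n_components)
    censored: np.ndarray  # keep-mask over all T volumes
    trial_types: tuple[str, ...] = TRIAL_TYPES
    rank_deficient: np.ndarray | None = None  # per fitted volume
    converged: bool = True
    n_volumes: int = 0

    @property
    def volumes(self) -> np.ndarray:
        """1-based volume index of each saved snapshot."""
        return np.arange(self.t_start, self.t_start + self.betas.shape[0])

    @property
    def n_components(self) -> int:
        return self.betas.shape[2]

    def beta_at(self, volume: int) -> np.ndarray:
        """(6, n_components) betas from the fit on volumes 1..volume."""
        i = volume - self.t_start
        if not 0 <= i < self.betas.shape[0]:
            raise IndexError(
                f"volume {volume} outside fitted range "
                f"[{self.t_start}, {self.t_start + self.betas.shape[0] - 1}]"
            )
        return self.betas[i]

    @property
    def full_task_betas(self) -> np.ndarray:
        """Betas from the fit on all acquired volumes (the full-task GLM)."""
        return self.betas[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long format: subject_id, volume, trial_type, component, beta."""
        n_t, n_types, n_comp = self.betas.shape
        vols = np.repeat(self.volumes, n_types * n_comp)
        types = np.tile(np.repeat(self.trial_types, n_comp), n_t)
        comps = np.tile(np.arange(1, n_comp + 1), n_t * n_types)
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "volume": vols,
                "trial_type": types,
                "component": comps,
                "beta": self.betas.ravel(),
            }
        )


class VolumeWiseGLM:
    """Model object for the volume-wise GLM of one subject.

    Parameters
    ----------
    dataset : SubjectDataset
        Labeled paradigm plus IC timecourses, motion, and FD.
    burn_in : int
        First candidate fitted volume (1-based); default the 50th.
    fd_threshold : float
        Framewise-displacement censoring threshold in mm.
    engine : {"direct", "qr"}
        "direct" (default) re-solves lstsq from scratch at every t; "qr"
        updates a QR factorization row by row.  Both give the minimum-norm
        OLS solution; at volumes flagged rank-deficient the minimum-norm
        answer is numerically delicate and the two paths may disagree in
        degenerate directions.
    ar1_rho : float or None
        If set, rows are AR(1)-prewhitened with this coefficient before
        censoring and fitting.
    """

    def __init__(
        self,
        dataset: SubjectDataset,
        burn_in: int = BURN_IN,
        fd_threshold: float = FD_THRESHOLD,
        engine: str = "direct",
        ar1_rho: float | None = None,
        drift_cutoff_hz: float = 1.0 / 128.0,
    ) -> None:
        if engine not in ("qr", "direct"):
            raise ValueError(f"unknown engine {engine!r}")
        self.dataset = dataset
        self.burn_in = burn_in
        self.fd_threshold = fd_threshold
        self.engine = engine
        self.ar1_rho = ar1_rho
        self.design = build_design(
            dataset.paradigm,
            dataset.motion6,
            tr=dataset.tr,
            n_volumes=dataset.n_volumes,
            drift_cutoff_hz=drift_cutoff_hz,
        )
        self.keep = censor_mask(dataset.fd, fd_threshold)

    def _prewhitened(self) -> tuple[np.ndarray, np.ndarray]:
        X = self.design.matrix
        Y = self.dataset.timecourses
        if self.ar1_rho:
            rho = self.ar1_rho
            Xw = X.copy()
            Yw = Y.copy()
            Xw[1:] -= rho * X[:-1]
            Yw[1:] -= rho * Y[:-1]
            Xw[0] *= np.sqrt(1 - rho**2)
            Yw[0] *= np.sqrt(1 - rho**2)
            return Xw, Yw
        return X, Y

    def fit(self) -> BetaTrajectory:
        X, Y = self._prewhitened()
        T = self.dataset.n_volumes
        t_start = first_valid_volume(self.design, self.burn_in)
        type_idx = [self.design.names.index(t) for t in TRIAL_TYPES]
        if t_start > T:
            return BetaTrajectory(
                subject_id=self.dataset.subject_id,
                t_start=t_start,
                betas=np.empty((0, len(TRIAL_TYPES), self.dataset.n_components)),
                censored=self.keep,
                converged=False,
                n_volumes=T,
            )

        n_t = T - t_start + 1
        betas = np.empty((n_t, len(TRIAL_TYPES), self.dataset.n_components))
        flags = np.zeros(n_t, dtype=bool)
        p = X.shape[1]

        if self.engine == "direct":
            for i, t in enumerate(range(t_start, T + 1)):
                b, deficient = fit_glm(Y[:t], X[:t], self.keep[:t])
                betas[i] = b[type_idx]
                flags[i] = deficient
        else:
            R = np.zeros((p, p))
            Z = np.zeros((p, self.dataset.n_components))
            for t in range(1, T + 1):
                if self.keep[t - 1]:
                    R, Z = _qr_append_row(R, Z, X[t - 1], Y[t - 1])
                if t >= t_start:
                    n_rows = int(self.keep[:t].sum())
                    if n_rows < 2:
                        raise InsufficientDataError(
                            f"only {n_rows} uncensored volumes at t={t}"
                        )
                    # X = QR with orthonormal-column Q gives
                    # pinv(X) y = pinv(R) Q'y, the minimum-norm solution.
                    b, _, rank, _ = np.linalg.lstsq(R, Z, rcond=None)
                    i = t - t_start
                    betas[i] = b[type_idx]
                    flags[i] = rank < p

        return BetaTrajectory(
            subject_id=self.dataset.subject_id,
            t_start=t_start,
            betas=betas,
            censored=self.keep,
            rank_deficient=flags,
            converged=True,
            n_volumes=T,
        )


def _qr_append_row(
    R: np.ndarray, Z: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One square-root RLS step: fold row (x, y) into (R, Q'Y).

    Re-triangularizes [R; x] with a fresh QR and applies the same rotation
    to [Z; y]; conditioning stays on the design scale throughout.
    """
    from scipy.linalg import qr

    p = R.shape[0]
    A = np.vstack([R, x[None, :]])
    B = np.vstack([Z, y[None, :]])
    Q, Rfull = qr(A, mode="full")
    return Rfull[:p], (Q.T @ B)[:p]


def run_vwglm(dataset: SubjectDataset, **kwargs) -> BetaTrajectory:
    """Functional wrapper: ``VolumeWiseGLM(dataset, **kwargs).fit()``."""
    return VolumeWiseGLM(dataset, **kwargs).fit()
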