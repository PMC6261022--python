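"""File formats: BIDS-style events.tsv, TSV matrices, beta tables, reports.

Everything is plain text (TSV/CSV/JSON) so every intermediate of the
pipeline is diffable.  Missing values are written as "n/a" in the BIDS
events dialect.  Readers validate schemas and raise :class:`SchemaError`
naming the file, line, and column at fault; writers and readers
round-trip losslessly (floats are written with 17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import Paradigm, TrialEvent
from .vwglm import BetaTrajectory

__all__ = [
    "SchemaError",
    "write_events",
    "read_events",
    "write_matrix",
    "read_matrix",
    "write_betas",
    "read_betas",
    "write_cohort_manifest",
    "write_decay_report",
    "write_ost_table",
    "write_cv_result",
    "results_table",
]

_FLOAT_FMT = "%.17g"
EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "base_type",
    "ssd_ms",
    "response",
    "rt_ms",
]


class SchemaError(ValueError):
    def __init__(self, path, message, line=None, column=None):
        loc = f"{path}"
        if line is not None:
            loc += f", line {line}"
        if column is not None:
            loc += f", column {column!r}"
        super().__init__(f"{loc}: {message}")
        self.path, self.line, self.column = str(path), line, column


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "n/a"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return _FLOAT_FMT % value
    return str(value)


def write_events(paradigm: Paradigm, path: str | Path) -> Path:
    """Write a paradigm as BIDS-dialect events.tsv plus a JSON sidecar
    carrying the scan geometry (tr, n_volumes, iti, rest blocks)."""
    path = Path(path)
    lines = ["\t".join(EVENT_COLUMNS)]
    for ev in paradigm.events:
        lines.append(
            "\t".join(
                [
                    _fmt(float(ev.onset)),
                    _fmt(float(ev.duration)),
                    ev.label,
                    ev.base_type,
                    _fmt(ev.ssd),
                    _fmt(ev.responded) if ev.is_task else "n/a",
                    _fmt(ev.rt),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "tr": paradigm.tr,
        "n_volumes": paradigm.n_volumes,
        "iti_ms": paradigm.iti,
        "rest_blocks": [list(b) for b in paradigm.rest_blocks],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")
    return path


def read_events(path: str | Path) -> Paradigm:
    """Read an events.tsv (+ optional sidecar) back into a Paradigm."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in EVENT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(path, f"missing columns {missing}", line=1)
        col = {name: header.index(name) for name in EVENT_COLUMNS}
        events = []
        prev_onset = -np.inf
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) != len(header):
                raise SchemaError(
                    path,
                    f"expected {len(header)} fields, found {len(parts)}",
                    line=lineno,
                )

            def get(name):
                return parts[col[name]]

            try:
                onset = float(get("onset"))
                duration = float(get("duration"))
            except ValueError as exc:
                raise SchemaError(path, str(exc), line=lineno, column="onset") from exc
            if onset <= prev_onset:
                raise SchemaError(
                    path,
                    f"onset {onset} not strictly increasing",
                    line=lineno,
                    column="onset",
                )
            prev_onset = onset
            ssd = get("ssd_ms")
            rt = get("rt_ms")
            resp = get("response")
            events.append(
                TrialEvent(
                    index=len(events),
                    onset=onset,
                    duration=duration,
                    base_type=get("base_type"),
                    ssd=None if ssd == "n/a" else float(ssd),
                    responded=resp == "1",
                    rt=None if rt == "n/a" else float(rt),
                    label=get("trial_type"),
                )
            )
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Paradigm(
        events=events,
        tr=meta.get("tr", 2.0),
        n_volumes=meta.get("n_volumes", 502),
        iti=meta.get("iti_ms", 2000.0),
        rest_blocks=[tuple(b) for b in meta.get("rest_blocks", [])],
    )


def write_matrix(
    matrix: np.ndarray, path: str | Path, columns: list[str] | None = None
) -> Path:
    """Write a 2-D array as TSV with a header row of column names."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] == 1 and matrix.shape[1] > 1 and columns is None:
        matrix = matrix.T
    if columns is None:
        columns = [f"c{i + 1}" for i in range(matrix.shape[1])]
    if len(columns) != matrix.shape[1]:
        raise ValueError("column count mismatch")
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in matrix:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a TSV matrix; returns (values, column names)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) != len(header):
                raise SchemaError(
                    path,
                    f"expected {len(header)} fields, found {len(parts)}",
                    line=lineno,
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise SchemaError(path, str(exc), line=lineno) from exc
    return np.array(rows), header


def write_betas(trajectory: BetaTrajectory, path: str | Path) -> Path:
    """Serialize a beta trajectory as long-format TSV plus JSON sidecar."""
    path = Path(path)
    df = trajectory.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "subject_id": trajectory.subject_id,
        "t_start": int(trajectory.t_start),
        "n_volumes": int(trajectory.n_volumes),
        "converged": bool(trajectory.converged),
        "censored_volumes": [
            int(v) for v in np.flatnonzero(~trajectory.censored) + 1
        ],
        "rank_deficient_volumes": (
            [int(v) for v in trajectory.volumes[trajectory.rank_deficient]]
            if trajectory.rank_deficient is not None
            else []
        ),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")
    return path


def read_betas(path: str | Path) -> BetaTrajectory:
    """Read a long-format beta TSV (+ sidecar) back into a BetaTrajectory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "volume", "trial_type", "component", "beta"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(path, f"missing columns {sorted(missing)}")
    if df["beta"].isna().any():
        line = int(df.index[df["beta"].isna()][0]) + 2
        raise SchemaError(path, "NaN beta value", line=line, column="beta")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    types = list(dict.fromkeys(df["trial_type"]))
    comps = sorted(df["component"].unique())
    vols = np.sort(df["volume"].unique())
    pivot = df.set_index(["volume", "trial_type", "component"])["beta"]
    betas = pivot.values.reshape(len(vols), len(types), len(comps))
    n_volumes = int(meta.get("n_volumes", vols.max()))
    keep = np.ones(n_volumes, dtype=bool)
    for v in meta.get("censored_volumes", []):
        keep[v - 1] = False
    t_start = int(meta.get("t_start", vols.min()))
    rank = np.zeros(len(vols), dtype=bool)
    for v in meta.get("rank_deficient_volumes", []):
        rank[int(v) - t_start] = True
    return BetaTrajectory(
        subject_id=str(df["subject_id"].iloc[0]),
        t_start=t_start,
        betas=betas,
        censored=keep,
        trial_types=tuple(types),
        rank_deficient=rank,
        converged=bool(meta.get("converged", True)),
        n_volumes=n_volumes,
    )


def write_cohort_manifest(subjects, path: str | Path) -> Path:
    """CSV manifest: subject_id, group, sex."""
    path = Path(path)
    rows = [
        {"subject_id": s.subject_id, "group": s.group, "sex": s.sex}
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_decay_report(fits, path: str | Path) -> Path:
    """TSV: subject_id, trial_type, n0, lambda, t_half, valid, n_points_used."""
    path = Path(path)
    rows = [
        {
            "subject_id": f.subject_id,
            "trial_type": f.trial_type,
            "n0": f.n0,
            "lambda": f.lam,
            "t_half": f.t_half,
            "valid": int(f.valid),
            "n_points_used": f.n_points_used,
            "n_excluded": f.n_excluded,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def write_ost_table(estimates, path: str | Path) -> Path:
    """TSV: subject_id, trial_type, k, stop_volume, clipped."""
    path = Path(path)
    rows = [
        {
            "subject_id": e.subject_id,
            "trial_type": e.trial_type,
            "k": e.k,
            "stop_volume": e.stop_volume,
            "clipped": int(e.clipped),
            "valid_fit": int(e.valid_fit),
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_cv_result(result, path: str | Path) -> Path:
    """JSON dump of one CVResult."""
    path = Path(path)
    payload = {
        "condition": result.condition,
        "n_resamples": result.n_resamples,
        "accuracy": result.accuracy,
        "accuracy_vote": result.accuracy_vote,
        "p_vs_chance": result.p_vs_chance,
        "pairwise_p": result.pairwise_p,
        "per_subject_score": result.per_subject_score.tolist(),
        "labels": result.labels.tolist(),
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def results_table(
    cells: dict[tuple[object, str], float],
    trial_types: tuple[str, ...] = ("GfSS", "GfFS", "SS", "FS"),
    k_values: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Arrange per-condition values in the half-life x trial-type layout.

    Rows are half-life 1-4 plus a full-task row; columns are the four
    task trial types (the full-task value, if present under
    ``("full", any)`` or ``("full", "")``, spans its row).
    """
    data = {}
    for tt in trial_types:
        data[tt] = [cells.get((k, tt), np.nan) for k in k_values]
    df = pd.DataFrame(data, index=[str(k) for k in k_values])
    full = [v for (k, _), v in cells.items() if k == "full"]
    df.loc["full task"] = full[0] if full else np.nan
    df.index.name = "half-life"
    return df
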