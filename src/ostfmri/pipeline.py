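"""End-to-end driver: simulation -> vwGLM -> decay/OST -> validation.

Each stage is a pure function of (config, seed); the run manifest records
the config hash, per-stage outputs, and every warning the pipeline can
emit (clipped OSTs, invalid decay fits, rank-deficient volumes, excluded
subjects), so a rerun with the same config and seed reproduces the same
files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as oio
from .config import RunConfig
from .decay import (
    TASK_TRIAL_TYPES,
    DecayFit,
    OSTEstimate,
    combined_ost,
    fit_decay,
    ost,
    ost_quartiles,
    soad,
)
from .synth import SubjectDataset, synth_cohort
from .validate import (
    BalancedLOOCV,
    CVResult,
    feature_matrix,
    residualize_sex,
    rt_correlation,
    test_pairwise,
    test_vs_chance,
)
from .vwglm import BetaTrajectory, VolumeWiseGLM

__all__ = [
    "SubjectAnalysis",
    "simulate_cohort",
    "analyze_subject",
    "classify_conditions",
    "behavior_correlations",
    "run_pipeline",
]


@dataclass
class SubjectAnalysis:
    """vwGLM + decay + OST results for one subject."""

    dataset: SubjectDataset
    trajectory: BetaTrajectory
    fits: dict[str, DecayFit]
    osts: dict[tuple[int, str], OSTEstimate]
    combined: dict[int, int]

    @property
    def excluded(self) -> bool:
        return not self.trajectory.converged


def simulate_cohort(config: RunConfig) -> list[SubjectDataset]:
    return synth_cohort(
        cohort=config.cohort,
        config=config.paradigm,
        race=config.race,
        seed=config.seed,
    )


def analyze_subject(dataset: SubjectDataset, config: RunConfig) -> SubjectAnalysis:
    """Fit the volume-wise GLM, model SoAD decay per trial type, and
    derive k-half-life stopping volumes."""
    vw = config.vwglm
    traj = VolumeWiseGLM(
        dataset,
        burn_in=vw.burn_in,
        fd_threshold=vw.fd_threshold,
        engine=vw.engine,
        ar1_rho=vw.ar1_rho,
        drift_cutoff_hz=vw.drift_cutoff_hz,
    ).fit()
    fits: dict[str, DecayFit] = {}
    osts: dict[tuple[int, str], OSTEstimate] = {}
    combined: dict[int, int] = {}
    if traj.converged:
        T = dataset.n_volumes
        for tt in TASK_TRIAL_TYPES:
            fits[tt] = fit_decay(soad(traj, tt), robust=config.decay.robust)
        for k in config.decay.k_values:
            per_type = {
                tt: ost(fits[tt], k, traj.t_start, T, anchor=config.decay.anchor)
                for tt in TASK_TRIAL_TYPES
            }
            for tt, est in per_type.items():
                osts[(k, tt)] = est
            combined[k] = combined_ost(per_type)
    return SubjectAnalysis(dataset, traj, fits, osts, combined)


def classify_conditions(
    analyses: list[SubjectAnalysis], config: RunConfig
) -> dict[tuple[object, str], CVResult]:
    """Balanced LOOCV for every (half-life, trial type) condition plus the
    full-task condition; chance and pairwise-vs-full tests applied."""
    val = config.validation
    kept = [a for a in analyses if not a.excluded]
    trajectories = [a.trajectory for a in kept]
    labels = np.array([a.dataset.group for a in kept])
    sexes = [a.dataset.sex for a in kept]

    def run(features: np.ndarray, condition: str, index: int) -> CVResult:
        if val.residualize_sex:
            features = residualize_sex(features, sexes)
        from .config import spawn_stage_seed

        res = BalancedLOOCV(
            features,
            labels,
            n_resamples=val.n_resamples,
            seed=spawn_stage_seed(config.seed, "loocv", index),
            condition=condition,
            standardize=val.standardize,
        ).fit()
        test_vs_chance(res)
        return res

    results: dict[tuple[object, str], CVResult] = {}
    full_volumes = [a.trajectory.n_volumes for a in kept]
    results[("full", "")] = run(
        feature_matrix(trajectories, full_volumes, "full_task"), "full_task", 0
    )
    index = 1
    for k in val.k_values:
        for tt in TASK_TRIAL_TYPES:
            stops = [a.osts[(k, tt)].stop_volume for a in kept]
            cond = f"{tt}_k{k}"
            results[(k, tt)] = run(
                feature_matrix(trajectories, stops, cond), cond, index
            )
            index += 1
    for key, res in results.items():
        if key != ("full", ""):
            test_pairwise(res, results[("full", "")], val.bonferroni_family)
    return results


def behavior_correlations(
    analyses: list[SubjectAnalysis], config: RunConfig
) -> dict[tuple[int, str], dict]:
    """Truncated-vs-full mean-RT Pearson correlations per condition
    (successful stops carry no RT and are skipped)."""
    kept = [a for a in analyses if not a.excluded]
    paradigms = [a.dataset.paradigm for a in kept]
    out: dict[tuple[int, str], dict] = {}
    for k in config.validation.k_values:
        for tt in ("GfSS", "GfFS", "FS"):
            stops = [a.osts[(k, tt)].stop_volume for a in kept]
            try:
                r, n_used, n_excl = rt_correlation(paradigms, stops, tt)
                out[(k, tt)] = {"r": r, "n_used": n_used, "n_excluded": n_excl}
            except Exception as exc:  # insufficient subjects after exclusion
                out[(k, tt)] = {"r": None, "error": str(exc)}
    return out


def _collect_warnings(analyses: list[SubjectAnalysis]) -> list[dict]:
    warnings = []
    for a in analyses:
        sid = a.dataset.subject_id
        if a.excluded:
            warnings.append({"class": "excluded_subject", "subject": sid})
            continue
        if a.trajectory.rank_deficient is not None and a.trajectory.rank_deficient.any():
            warnings.append(
                {
                    "class": "rank_deficient",
                    "subject": sid,
                    "n_volumes": int(a.trajectory.rank_deficient.sum()),
                }
            )
        for tt, f in a.fits.items():
            if not f.valid:
                warnings.append(
                    {"class": "invalid_decay", "subject": sid, "trial_type": tt}
                )
        for (k, tt), e in a.osts.items():
            if e.clipped:
                warnings.append(
                    {
                        "class": "clipped_ost",
                        "subject": sid,
                        "trial_type": tt,
                        "k": k,
                    }
                )
    return warnings


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage and write all tabular outputs; returns the manifest."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "outputs": {},
        "warnings": [],
    }

    subjects = simulate_cohort(config)
    sim_dir = outdir / "sim"
    sim_dir.mkdir(exist_ok=True)
    for s in subjects:
        oio.write_events(s.paradigm, sim_dir / f"{s.subject_id}_events.tsv")
        oio.write_matrix(
            s.timecourses,
            sim_dir / f"{s.subject_id}_timecourses.tsv",
            [f"IC{i + 1}" for i in range(s.n_components)],
        )
        oio.write_matrix(
            s.motion6,
            sim_dir / f"{s.subject_id}_motion.tsv",
            ["tx", "ty", "tz", "rx", "ry", "rz"],
        )
        oio.write_matrix(s.fd[:, None], sim_dir / f"{s.subject_id}_fd.tsv", ["fd"])
    oio.write_cohort_manifest(subjects, sim_dir / "cohort.csv")
    manifest["outputs"]["sim"] = str(sim_dir)

    analyses = [analyze_subject(s, config) for s in subjects]
    beta_dir = outdir / "betas"
    beta_dir.mkdir(exist_ok=True)
    for a in analyses:
        if not a.excluded:
            oio.write_betas(a.trajectory, beta_dir / f"{a.dataset.subject_id}_betas.tsv")
    manifest["outputs"]["betas"] = str(beta_dir)

    fits = [f for a in analyses for f in a.fits.values()]
    oio.write_decay_report(fits, outdir / "decay.tsv")
    estimates = [e for a in analyses for e in a.osts.values()]
    oio.write_ost_table(estimates, outdir / "ost.tsv")
    manifest["outputs"]["decay"] = str(outdir / "decay.tsv")
    manifest["outputs"]["ost"] = str(outdir / "ost.tsv")

    # box-plot quartiles of the combined OST per k, and per-group at k=1
    summary: dict = {"per_k": {}, "per_group_k1": {}}
    kept = [a for a in analyses if not a.excluded]
    for k in config.decay.k_values:
        vals = [a.combined[k] for a in kept]
        summary["per_k"][str(k)] = ost_quartiles(np.array(vals))
    for grp in ("CD", "Con"):
        vals = [
            a.osts[(1, tt)].stop_volume
            for a in kept
            if a.dataset.group == grp
            for tt in TASK_TRIAL_TYPES
        ]
        if vals:
            summary["per_group_k1"][grp] = ost_quartiles(np.array(vals))
    (outdir / "ost_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    manifest["outputs"]["ost_summary"] = str(outdir / "ost_summary.json")

    cv = classify_conditions(analyses, config)
    cv_dir = outdir / "cv"
    cv_dir.mkdir(exist_ok=True)
    cells = {}
    for key, res in cv.items():
        oio.write_cv_result(res, cv_dir / f"{res.condition}.json")
        cells[key if key[0] != "full" else ("full", "")] = res.accuracy
    oio.results_table(cells).to_csv(outdir / "accuracy_table.tsv", sep="\t")
    manifest["outputs"]["cv"] = str(cv_dir)
    manifest["outputs"]["accuracy_table"] = str(outdir / "accuracy_table.tsv")

    behave = behavior_correlations(analyses, config)
    (outdir / "rt_correlations.json").write_text(
        json.dumps({f"{k}:{tt}": v for (k, tt), v in behave.items()}, indent=1)
        + "\n"
    )
    manifest["outputs"]["rt_correlations"] = str(outdir / "rt_correlations.json")

    manifest["warnings"] = _collect_warnings(analyses)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
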