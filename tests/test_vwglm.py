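"""Design construction, censoring, and the volume-wise GLM engines."""

import numpy as np
import pytest

from ostfmri.paradigm import ParadigmConfig, generate_paradigm, label_trials, simulate_behavior
from ostfmri.synth import SubjectDataset, synth_subject
from ostfmri.vwglm import (
    InsufficientDataError,
    VolumeWiseGLM,
    build_design,
    censor_mask,
    first_valid_volume,
    fit_glm,
)


@pytest.fixture(scope="module")
def design(small_subject):
    return build_design(
        small_subject.paradigm,
        small_subject.motion6,
        tr=small_subject.tr,
        n_volumes=small_subject.n_volumes,
    )


class TestDesign:
    def test_24_motion_columns(self, design):
        motion_cols = [n for n in design.names if n.startswith("mot") and n != "motor"]
        assert len(motion_cols) == 24
        for block in ("raw", "sq", "diff", "diffsq"):
            assert sum(n.split("_", 1)[1] == block for n in motion_cols) == 6

    def test_trial_type_and_motor_columns_present(self, design):
        for name in ("instruction", "GG", "GfSS", "GfFS", "SS", "FS", "motor"):
            assert name in design.names

    def test_all_go_paradigm_zero_stop_columns(self):
        cfg = ParadigmConfig(n_trials=20, n_stop=0, n_volumes=80)
        p = label_trials(simulate_behavior(generate_paradigm(cfg, seed=0), seed=0))
        d = build_design(p, np.zeros((80, 6)))
        for name in ("SS", "FS", "GfSS", "GfFS"):
            assert np.all(d.column(name) == 0.0)

    def test_constant_motion_has_zero_diff_columns(self, small_subject):
        m6 = np.full((small_subject.n_volumes, 6), 0.3)
        d = build_design(small_subject.paradigm, m6, tr=2.0,
                         n_volumes=small_subject.n_volumes)
        for i in range(1, 7):
            assert np.all(d.column(f"mot{i}_diff") == 0.0)
            assert np.all(d.column(f"mot{i}_diffsq") == 0.0)

    def test_columns_zero_before_first_event(self, design, small_subject):
        first_fs = min(
            e.onset for e in small_subject.paradigm.events if e.label == "FS"
        )
        n_before = int(first_fs // small_subject.tr)
        assert np.all(design.column("FS")[:n_before] == 0.0)

    def test_event_beyond_scan_rejected(self, small_subject):
        with pytest.raises(ValueError, match="beyond scan end"):
            build_design(small_subject.paradigm, np.zeros((40, 6)),
                         tr=2.0, n_volumes=40)


class TestCensoring:
    @pytest.mark.parametrize(
        "fd,expected",
        [
            ([0.1, 0.6, 0.4], [True, False, True]),
            ([0.5], [True]),  # boundary: rule is strictly greater than
            ([0.0, 0.0], [True, True]),
        ],
    )
    def test_threshold_rule(self, fd, expected):
        assert censor_mask(np.array(fd)).tolist() == expected

    def test_invalid_fd_rejected(self):
        with pytest.raises(ValueError):
            censor_mask(np.array([0.1, -0.2]))
        with pytest.raises(ValueError):
            censor_mask(np.array([np.nan]))

    def test_censoring_idempotent(self, small_subject):
        """Censoring already-censored data changes nothing: any FD value
        above threshold marks the same volumes, so the fit is invariant
        to how far above threshold a censored volume sits."""
        mask = censor_mask(small_subject.fd)
        assert mask.sum() < mask.size  # fixture does censor something
        fd2 = np.where(mask, small_subject.fd, 9.9)
        assert np.array_equal(censor_mask(fd2), mask)
        sub2 = SubjectDataset(
            small_subject.subject_id,
            small_subject.timecourses,
            small_subject.tr,
            small_subject.motion6,
            fd2,
            small_subject.paradigm,
            small_subject.group,
            small_subject.sex,
        )
        traj1 = VolumeWiseGLM(small_subject).fit()
        traj2 = VolumeWiseGLM(sub2).fit()
        assert np.array_equal(traj1.betas, traj2.betas)


class TestFirstValidVolume:
    def test_default_burn_in(self, design):
        # all trial types occur before the 50th volume in this paradigm
        assert first_valid_volume(design) == 50

    def test_missing_trial_type_sentinel(self):
        cfg = ParadigmConfig(n_trials=20, n_stop=0, n_volumes=80)
        p = label_trials(simulate_behavior(generate_paradigm(cfg, seed=0), seed=0))
        d = build_design(p, np.zeros((80, 6)))
        assert first_valid_volume(d) == 81  # T + 1: SS/FS never occur

    def test_late_first_event_pushes_start(self, design):
        # artificially blank the FS regressor before volume 80
        import copy

        d2 = copy.deepcopy(design)
        col = d2.names.index("FS")
        d2.matrix[:79, col] = 0.0
        assert first_valid_volume(d2) >= 80

    def test_non_converged_subject_flagged(self):
        cfg = ParadigmConfig(n_trials=20, n_stop=0, n_volumes=80)
        sub = synth_subject("s", config=cfg, seed=1)
        traj = VolumeWiseGLM(sub).fit()
        assert not traj.converged
        assert traj.betas.shape[0] == 0


class TestFitGLM:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 8))
        b = rng.normal(size=(8, 3))
        betas, deficient = fit_glm(X @ b, X)
        assert not deficient
        assert np.abs(betas - b).max() < 1e-8

    def test_duplicate_column_flagged_fit_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=(60, 2))
        Xd = np.hstack([X, X[:, [2]]])
        b1, d1 = fit_glm(y, X)
        b2, d2 = fit_glm(y, Xd)
        assert not d1 and d2
        assert np.abs(X @ b1 - Xd @ b2).max() < 1e-8  # same fitted values

    def test_matches_normal_equations_oracle(self):
        """Independent oracle: solve X'X b = X'y directly."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            X = rng.normal(size=(200, 10))
            Y = rng.normal(size=(200, 4))
            betas, _ = fit_glm(Y, X)
            oracle = np.linalg.solve(X.T @ X, X.T @ Y)
            assert np.abs(betas - oracle).max() < 1e-8

    def test_censored_rows_deleted(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        Y = rng.normal(size=(50, 2))
        mask = np.ones(50, dtype=bool)
        mask[10:20] = False
        b1, _ = fit_glm(Y, X, mask)
        b2, _ = fit_glm(Y[mask], X[mask])
        assert np.array_equal(b1, b2)

    def test_insufficient_rows(self):
        with pytest.raises(InsufficientDataError):
            fit_glm(np.ones((1, 2)), np.ones((1, 3)))


class TestVolumeWise:
    def test_snapshot_count(self, small_trajectory, small_subject):
        T = small_subject.n_volumes
        assert small_trajectory.betas.shape[0] == T - small_trajectory.t_start + 1

    def test_final_volume_equals_full_glm(self, small_subject, small_trajectory):
        glm = VolumeWiseGLM(small_subject)
        X = glm.design.matrix
        Y = small_subject.timecourses
        betas, _ = fit_glm(Y, X, glm.keep)
        type_idx = [glm.design.names.index(t) for t in small_trajectory.trial_types]
        assert np.abs(small_trajectory.full_task_betas - betas[type_idx]).max() < 1e-8

    def test_noiseless_trajectory_constant(self, noiseless_subject):
        traj = VolumeWiseGLM(noiseless_subject).fit()
        ok = ~traj.rank_deficient
        spread = traj.betas[ok].max(axis=0) - traj.betas[ok].min(axis=0)
        assert spread.max() < 1e-5

    def test_engines_agree_when_well_conditioned(self, well_conditioned_subject):
        """The QR row-append fast path must equal the from-scratch solve
        at every fitted volume on a numerically full-rank design."""
        a = VolumeWiseGLM(well_conditioned_subject, engine="direct").fit()
        b = VolumeWiseGLM(well_conditioned_subject, engine="qr").fit()
        assert not a.rank_deficient.any()
        assert np.abs(a.betas - b.betas).max() < 1e-8

    def test_incremental_equals_from_scratch_each_t(self, well_conditioned_subject):
        """Spot-check the trajectory against independent full solves."""
        traj = VolumeWiseGLM(well_conditioned_subject, engine="qr").fit()
        glm = VolumeWiseGLM(well_conditioned_subject)
        X, Y = glm.design.matrix, well_conditioned_subject.timecourses
        type_idx = [glm.design.names.index(t) for t in traj.trial_types]
        for t in (traj.t_start, 90, 120, traj.n_volumes):
            oracle, _ = fit_glm(Y[:t], X[:t])
            assert np.abs(traj.beta_at(t) - oracle[type_idx]).max() < 1e-8

    def test_long_format_round_trip(self, small_trajectory):
        df = small_trajectory.to_frame()
        assert set(df.columns) == {
            "subject_id", "volume", "trial_type", "component", "beta"
        }
        n_t, n_types, n_comp = small_trajectory.betas.shape
        assert len(df) == n_t * n_types * n_comp
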