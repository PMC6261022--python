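"""Feature assembly, balanced LOOCV, rank tests, RT correlations."""

import itertools

import numpy as np
import pytest
from scipy import stats

from ostfmri.decay import TASK_TRIAL_TYPES
from ostfmri.paradigm import Paradigm, TrialEvent
from ostfmri.validate import (
    BalancedLOOCV,
    CVResult,
    NoRTError,
    balanced_loocv,
    extract_features,
    ost_group_compare,
    residualize_sex,
    rt_correlation,
    signed_rank_p,
)
from ostfmri.validate import test_pairwise as pairwise_test
from ostfmri.validate import test_vs_chance as chance_test
from ostfmri.vwglm import BetaTrajectory


def _trajectory(n_comp=22, n_t=30, t_start=50, subject="s"):
    rng = np.random.default_rng(hash(subject) % 2**31)
    return BetaTrajectory(
        subject_id=subject,
        t_start=t_start,
        betas=rng.normal(size=(n_t, 6, n_comp)),
        censored=np.ones(t_start + n_t - 1, dtype=bool),
        n_volumes=t_start + n_t - 1,
    )


class TestFeatures:
    def test_88_dimensions_with_22_components(self):
        fv = extract_features(_trajectory(), stop_volume=60)
        assert fv.values.shape == (88,)

    def test_scaling_with_component_count(self):
        assert extract_features(_trajectory(n_comp=1), 55).values.shape == (4,)

    def test_last_volume_equals_full_task(self):
        tr = _trajectory()
        full = extract_features(tr, tr.n_volumes)
        j = [tr.trial_types.index(t) for t in TASK_TRIAL_TYPES]
        assert np.array_equal(full.values, tr.full_task_betas[j].ravel())

    def test_concatenation_order(self):
        tr = _trajectory(n_comp=2)
        fv = extract_features(tr, 60)
        b = tr.beta_at(60)
        expected = np.concatenate(
            [b[tr.trial_types.index(t)] for t in ("GfSS", "GfFS", "SS", "FS")]
        )
        assert np.array_equal(fv.values, expected)

    def test_stop_before_fit_start_rejected(self):
        with pytest.raises(ValueError):
            extract_features(_trajectory(t_start=50), 49)


class TestResidualizeSex:
    def test_pure_sex_effect_removed(self):
        sex = np.array(["M"] * 10 + ["F"] * 10)
        features = np.where(sex == "M", 2.0, -1.0)[:, None] * np.ones((20, 5))
        res = residualize_sex(features, sex)
        assert np.abs(res).max() < 1e-10

    def test_additive_offset_orthogonalized(self):
        rng = np.random.default_rng(4)
        sex = np.array(["M"] * 12 + ["F"] * 8)
        features = rng.normal(size=(20, 6))
        features[sex == "M", 2] += 0.7
        res = residualize_sex(features, sex)
        gap = res[sex == "M", 2].mean() - res[sex == "F", 2].mean()
        assert abs(gap) < 1e-10

    def test_sex_independent_features_mean_centered(self):
        rng = np.random.default_rng(5)
        sex = np.array(["M", "F"] * 10)
        base = np.tile(rng.normal(size=(1, 4)), (20, 1))
        res = residualize_sex(base, sex)
        assert np.abs(res).max() < 1e-10  # constant columns center to zero

    def test_single_sex_rejected(self):
        with pytest.raises(ValueError):
            residualize_sex(np.ones((5, 2)), ["M"] * 5)


def _cohort_features(n_cd=40, n_con=27, effect=0.0, seed=0, d=10):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_cd + n_con, d))
    X[:n_cd, : d // 2] += effect
    y = np.array(["CD"] * n_cd + ["Con"] * n_con)
    return X, y


class TestBalancedLOOCV:
    def test_training_set_sizes_and_balance(self):
        X, y = _cohort_features()
        model = BalancedLOOCV(X, y, n_resamples=5, seed=0)
        rng = np.random.default_rng(0)
        cd_test = int(np.flatnonzero(y == "CD")[0])
        con_test = int(np.flatnonzero(y == "Con")[0])
        for test_idx, expected in ((cd_test, 54), (con_test, 52)):
            for _ in range(10):
                train = model.draw_training_set(test_idx, rng)
                assert len(train) == expected
                assert test_idx not in train
                labels = y[train]
                assert (labels == "CD").sum() == (labels == "Con").sum()
                assert len(set(train)) == len(train)  # no replacement

    def test_deterministic_given_seed(self):
        X, y = _cohort_features(n_cd=8, n_con=6, effect=1.0, seed=1)
        a = balanced_loocv(X, y, n_resamples=15, seed=3)
        b = balanced_loocv(X, y, n_resamples=15, seed=3)
        assert np.array_equal(a.per_subject_score, b.per_subject_score)

    def test_separable_cohort_high_accuracy(self):
        X, y = _cohort_features(n_cd=12, n_con=9, effect=4.0, seed=2)
        res = balanced_loocv(X, y, n_resamples=25, seed=0)
        assert res.accuracy > 0.9

    def test_null_cohort_near_chance(self):
        accs = []
        for seed in range(5):
            X, y = _cohort_features(n_cd=12, n_con=9, effect=0.0, seed=seed)
            accs.append(balanced_loocv(X, y, n_resamples=25, seed=seed).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_minority_too_small_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(Exception):
            BalancedLOOCV(X, np.array(["a", "a", "b"]), 5, 0)

    def test_scores_are_fractions(self):
        X, y = _cohort_features(n_cd=6, n_con=5, effect=0.5, seed=3)
        res = balanced_loocv(X, y, n_resamples=8, seed=1)
        assert np.all((res.per_subject_score >= 0) & (res.per_subject_score <= 1))
        assert 0.0 <= res.accuracy <= 1.0
        assert "accuracy" in res.summary()


def _exact_signed_rank_greater(values, null):
    """Enumeration oracle: distribution of W+ over all 2^n sign patterns."""
    d = np.asarray(values, float) - null
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w >= w_obs:
            count += 1
    return count / 2**n


class TestRankTests:
    def test_signed_rank_matches_enumeration(self):
        """Exact p for n=10 equals brute-force enumeration over all
        2^10 sign assignments."""
        rng = np.random.default_rng(11)
        for _ in range(3):
            v = np.round(rng.normal(0.55, 0.15, 10), 3)
            v = v[v != 0.5]
            assert signed_rank_p(v, null=0.5, alternative="greater") == pytest.approx(
                _exact_signed_rank_greater(v, 0.5), abs=1e-12
            )

    def test_all_scores_at_null_gives_p_one(self):
        res = CVResult("c", np.full(10, 0.5), np.array(["a"] * 10), 10)
        assert chance_test(res) == 1.0

    def test_strong_evidence_small_p(self):
        res = CVResult("c", np.full(67, 1.0), np.array(["a"] * 67), 10)
        assert chance_test(res) < 1e-10

    def test_symmetric_scores_not_significant(self):
        scores = 0.5 + np.concatenate([np.linspace(0.01, 0.2, 10),
                                       -np.linspace(0.01, 0.2, 10)])
        res = CVResult("c", scores, np.array(["a"] * 20), 10)
        assert chance_test(res) > 0.4

    def test_pairwise_identical_capped_at_one(self):
        a = CVResult("a", np.linspace(0.4, 0.8, 12), np.array(["x"] * 12), 10)
        b = CVResult("b", np.linspace(0.4, 0.8, 12), np.array(["x"] * 12), 10)
        assert pairwise_test(a, b, n_comparisons=16) == 1.0

    def test_pairwise_uniform_improvement(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.3, 0.7, 14)
        lift = rng.uniform(0.05, 0.3, 14)  # distinct positive differences
        a = CVResult("a", base + lift, np.array(["x"] * 14), 10)
        b = CVResult("b", base, np.array(["x"] * 14), 10)
        raw = signed_rank_p(a.per_subject_score - b.per_subject_score)
        assert raw == pytest.approx(2.0**-14, rel=1e-9)

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(9)
        a = CVResult("a", rng.uniform(0.4, 0.6, 10), np.array(["x"] * 10), 10)
        b = CVResult("b", rng.uniform(0.4, 0.6, 10), np.array(["x"] * 10), 10)
        assert pairwise_test(a, b, n_comparisons=16) <= 1.0

    def test_ranksum_disjoint_supports_exact_tail(self):
        """Completely separated groups of 10: p equals the two-sided
        extreme tail 2/C(20,10)."""
        x = np.arange(10.0)
        y = np.arange(100.0, 110.0)
        from math import comb

        assert ost_group_compare(x, y) == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_ranksum_identical_distributions(self):
        rng = np.random.default_rng(2)
        ps = [
            ost_group_compare(rng.normal(size=30), rng.normal(size=30))
            for _ in range(10)
        ]
        assert np.median(ps) > 0.2

    def test_ranksum_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ost_group_compare(np.array([]), np.array([1.0]))


def _rt_paradigm(rts, label="GfSS", tr=2.0, n_volumes=100):
    events = []
    for i, rt in enumerate(rts):
        events.append(
            TrialEvent(index=i, onset=3.0 * i, base_type="go",
                       responded=True, rt=float(rt), label=label)
        )
    return Paradigm(events=events, tr=tr, n_volumes=n_volumes)


class TestRTCorrelation:
    def test_ss_has_no_rt(self):
        with pytest.raises(NoRTError):
            rt_correlation([], [], "SS")

    def test_full_window_subjects_excluded(self):
        pars = [_rt_paradigm(np.linspace(300, 500, 20)) for _ in range(5)]
        with pytest.raises(Exception):
            # every subject's window spans the full task -> empty set
            rt_correlation(pars, [100] * 5, "GfSS")

    def test_half_window_strong_correlation(self):
        rng = np.random.default_rng(8)
        pars = []
        for _ in range(30):
            base = rng.uniform(350, 650)
            pars.append(_rt_paradigm(base + rng.normal(0, 30, 20)))
        r, n_used, n_excl = rt_correlation(pars, [50] * 30, "GfSS")
        assert n_used == 30 and n_excl == 0
        assert r > 0.9
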