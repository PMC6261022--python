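"""Validation of OST-truncated neural features.

Primary validation: features are the four task trial types' beta weights
(GfSS, GfFS, SS, FS; 22 components each, 88 dimensions) read out at a
stopping volume, classified CD vs Con with a linear soft-margin SVM under
balanced leave-one-out cross-validation — the majority group is randomly
subsampled to the minority size in every training set, 1000 independent
draws per left-out subject, and the 1000 test predictions are averaged
into that subject's score.  Accuracy is tested against chance with a
one-sided one-sample Wilcoxon signed-rank test (null = 0.5), and
truncated-vs-full conditions are compared with pairwise signed-rank tests
under Bonferroni correction.

Secondary validation: cumulative mean reaction times inside the truncated
window are correlated (Pearson) with full-task mean RTs across subjects;
successful-stop trials yield no RT and are excluded by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .decay import TASK_TRIAL_TYPES
from .paradigm import Paradigm
from .vwglm import BetaTrajectory, InsufficientDataError

__all__ = [
    "FeatureVector",
    "CVResult",
    "BalancedLOOCV",
    "extract_features",
    "feature_matrix",
    "residualize_sex",
    "balanced_loocv",
    "test_vs_chance",
    "test_pairwise",
    "signed_rank_p",
    "ost_group_compare",
    "rt_correlation",
    "NoRTError",
]


class NoRTError(ValueError):
    """Successful-stop trials have no reaction time by definition."""


@dataclass
class FeatureVector:
    """One subject's concatenated beta-weight feature at a stop volume."""

    subject_id: str
    values: np.ndarray
    stop_volume: int
    condition: str = "full_task"


def extract_features(
    trajectory: BetaTrajectory, stop_volume: int, condition: str = "full_task"
) -> FeatureVector:
    """Betas of GfSS, GfFS, SS, FS at ``stop_volume``, concatenated.

    Order is (GfSS, GfFS, SS, FS) x component, giving 4 x n_components
    entries (88 with the default 22 usable components).
    """
    if stop_volume < trajectory.t_start:
        raise ValueError(
            f"stop volume {stop_volume} precedes first fitted volume "
            f"{trajectory.t_start}"
        )
    b = trajectory.beta_at(stop_volume)
    rows = [b[trajectory.trial_types.index(t)] for t in TASK_TRIAL_TYPES]
    return FeatureVector(
        subject_id=trajectory.subject_id,
        values=np.concatenate(rows),
        stop_volume=stop_volume,
        condition=condition,
    )


def feature_matrix(
    trajectories: list[BetaTrajectory],
    stop_volumes: list[int] | np.ndarray,
    condition: str = "full_task",
) -> np.ndarray:
    """Stack per-subject feature vectors into (n_subjects, 4*n_components)."""
    return np.vstack(
        [
            extract_features(tr, int(sv), condition).values
            for tr, sv in zip(trajectories, stop_volumes, strict=True)
        ]
    )


def residualize_sex(features: np.ndarray, sex: list[str] | np.ndarray) -> np.ndarray:
    """Regress participant sex out of every feature dimension.

    Ordinary regression of each column on an intercept plus a sex
    indicator; returns the residuals, whose within-sex means are zero in
    every dimension.
    """
    sex = np.asarray(sex)
    levels = np.unique(sex)
    if levels.size < 2:
        raise ValueError("cohort contains a single sex; covariate is degenerate")
    X = np.column_stack([np.ones(len(sex)), (sex == levels[0]).astype(float)])
    beta, *_ = np.linalg.lstsq(X, features, rcond=None)
    return features - X @ beta


@dataclass
class CVResult:
    """Balanced-LOOCV output for one feature condition.

    ``per_subject_score[i]`` is the fraction of the resampled classifiers
    that predicted subject i's true group label; ``accuracy`` is the mean
    of these fractional scores and ``accuracy_vote`` the mean of
    majority-vote correctness (score > 0.5, ties counted half).
    """

    condition: str
    per_subject_score: np.ndarray
    labels: np.ndarray
    n_resamples: int
    p_vs_chance: float | None = None
    pairwise_p: float | None = None

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.per_subject_score))

    @property
    def accuracy_vote(self) -> float:
        s = self.per_subject_score
        return float(np.mean((s > 0.5) + 0.5 * (s == 0.5)))

    def summary(self) -> str:
        lines = [
            f"Balanced LOOCV ({self.n_resamples} resampled training sets per fold)",
            f"  condition:          {self.condition}",
            f"  subjects:           {len(self.per_subject_score)}",
            f"  accuracy (mean):    {self.accuracy:.4f}",
            f"  accuracy (vote):    {self.accuracy_vote:.4f}",
        ]
        if self.p_vs_chance is not None:
            lines.append(f"  p vs chance (0.5):  {self.p_vs_chance:.4g}")
        if self.pairwise_p is not None:
            lines.append(f"  p vs full task:     {self.pairwise_p:.4g}")
        return "\n".join(lines)


class BalancedLOOCV:
    """Balanced leave-one-out SVM cross-validation model.

    For each left-out subject the majority group (CD) is subsampled to
    the minority size — 27+27 = 54 training subjects when the test
    subject is CD, 26+26 = 52 when Con — ``n_resamples`` times, a linear
    soft-margin SVM (cost 1) is trained on each draw, and the fraction of
    draws predicting the true label becomes the subject's score.
    Deterministic given (features, labels, seed).  Features are used as
    given (no standardization) unless ``standardize`` is set.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels: np.ndarray | list[str],
        n_resamples: int = 1000,
        seed: int = 0,
        condition: str = "full_task",
        standardize: bool = False,
        C: float = 1.0,
    ) -> None:
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        self.n_resamples = n_resamples
        self.seed = seed
        self.condition = condition
        self.standardize = standardize
        self.C = C
        uniq, cnt = np.unique(self.labels, return_counts=True)
        if uniq.size != 2:
            raise ValueError(f"need exactly two groups, got {list(uniq)}")
        if cnt[0] == cnt[1]:
            self._minority, self._majority = uniq[0], uniq[1]
        else:
            self._minority = uniq[np.argmin(cnt)]
            self._majority = uniq[np.argmax(cnt)]
        if cnt.min() < 2:
            raise InsufficientDataError("minority group must have >= 2 members")

    def draw_training_set(self, test_index: int, rng: np.random.Generator) -> np.ndarray:
        """One balanced training draw for a given left-out subject.

        The test subject is removed from its group first, then the
        majority group is subsampled without replacement to the minority
        size, so both groups contribute equally many training subjects.
        """
        y = self.labels
        min_idx = np.flatnonzero(y == self._minority)
        maj_idx = np.flatnonzero(y == self._majority)
        if y[test_index] == self._majority:
            pool_maj = maj_idx[maj_idx != test_index]
            pool_min = min_idx
        else:
            pool_maj = maj_idx
            pool_min = min_idx[min_idx != test_index]
        k = len(pool_min)
        return np.concatenate(
            [rng.choice(pool_maj, size=k, replace=False), pool_min]
        )

    def fit(self) -> CVResult:
        X = self.features
        if self.standardize:
            X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1)
        y = self.labels
        n = len(y)
        gram = X @ X.T  # linear kernel, precomputed once
        rng = np.random.default_rng(self.seed)
        scores = np.empty(n)
        for i in range(n):
            correct = 0
            for _ in range(self.n_resamples):
                train = self.draw_training_set(i, rng)
                svm = SVC(kernel="precomputed", C=self.C)
                svm.fit(gram[np.ix_(train, train)], y[train])
                pred = svm.predict(gram[np.ix_([i], train)])[0]
                correct += pred == y[i]
            scores[i] = correct / self.n_resamples
        return CVResult(
            condition=self.condition,
            per_subject_score=scores,
            labels=y.copy(),
            n_resamples=self.n_resamples,
        )


def balanced_loocv(
    features: np.ndarray,
    labels: np.ndarray | list[str],
    n_resamples: int = 1000,
    seed: int = 0,
    **kwargs,
) -> CVResult:
    """Functional wrapper around :class:`BalancedLOOCV`."""
    return BalancedLOOCV(features, labels, n_resamples, seed, **kwargs).fit()


def signed_rank_p(
    values: np.ndarray, null: float = 0.0, alternative: str = "greater"
) -> float:
    """Wilcoxon signed-rank p-value against a point null.

    Exact distribution when n <= 25 with no zeros or tied magnitudes,
    normal approximation with continuity correction otherwise.  If every
    value equals the null the test is undefined and p = 1 is reported.
    """
    d = np.asarray(values, dtype=float) - null
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks_unique = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= 25 and ranks_unique) else "approx"
    res = stats.wilcoxon(
        d, alternative=alternative, method=method, correction=(method == "approx")
    )
    return float(res.pvalue)


def test_vs_chance(result: CVResult) -> float:
    """One-sided signed-rank test of per-subject scores against 0.5."""
    p = signed_rank_p(result.per_subject_score, null=0.5, alternative="greater")
    result.p_vs_chance = p
    return p


def test_pairwise(
    result_a: CVResult, result_b: CVResult, n_comparisons: int = 16
) -> float:
    """Paired one-sided signed-rank test (a > b), Bonferroni-adjusted.

    p is multiplied by the comparison-family size (default 16: 4 trial
    types x 4 half-lives) and capped at 1.
    """
    a, b = result_a.per_subject_score, result_b.per_subject_score
    if a.shape != b.shape:
        raise ValueError("score vectors must pair up subject-by-subject")
    p = signed_rank_p(a - b, null=0.0, alternative="greater")
    adj = min(p * n_comparisons, 1.0)
    result_a.pairwise_p = adj
    return adj


def ost_group_compare(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two OST samples.

    Exact distribution when both groups have n <= 25 and there are no
    ties; normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(x.size, y.size) <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def _mean_rt(paradigm: Paradigm, trial_type: str, before_s: float | None) -> float:
    rts = [
        ev.rt
        for ev in paradigm.task_events
        if ev.label == trial_type
        and ev.rt is not None
        and (before_s is None or ev.onset < before_s)
    ]
    return float(np.mean(rts)) if rts else np.nan


def rt_correlation(
    paradigms: list[Paradigm],
    stop_volumes: list[int] | np.ndarray,
    trial_type: str,
) -> tuple[float, int, int]:
    """Pearson correlation of truncated vs full-task mean reaction times.

    For each subject, the mean RT of ``trial_type`` trials with onset
    before stop_volume * TR is correlated (across subjects) with the mean
    over all trials.  Subjects whose truncated window spans the whole
    acquisition are excluded — their correlation would be trivially
    perfect.  Returns (r, n_used, n_excluded).
    """
    if trial_type == "SS":
        raise NoRTError("SS trials are successful inhibitions: no RT exists")
    trunc, full = [], []
    n_excluded = 0
    for par, sv in zip(paradigms, stop_volumes, strict=True):
        if sv >= par.n_volumes:
            n_excluded += 1
            continue
        trunc.append(_mean_rt(par, trial_type, before_s=sv * par.tr))
        full.append(_mean_rt(par, trial_type, before_s=None))
    trunc_a, full_a = np.asarray(trunc), np.asarray(full)
    ok = np.isfinite(trunc_a) & np.isfinite(full_a)
    n_excluded += int((~ok).sum())
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"only {int(ok.sum())} subjects remain after exclusions"
        )
    r = stats.pearsonr(trunc_a[ok], full_a[ok]).statistic
    return float(r), int(ok.sum()), n_excluded
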