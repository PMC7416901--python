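"""Validation statistics for epoched pupil data.

* :func:`lme_scan` — a linear mixed model (by-participant random intercept
  and slopes) fitted at every sample of the epoch axis; samples whose fixed
  effect exceeds |t| > 2 are collected into maximal runs and runs shorter
  than 200 ms are discarded.  No explicit p-values are produced; the
  |t|-plus-duration rule is the significance criterion.
* :func:`extract_features` — per-trial signed extrema (max dilation, max
  constriction) and their latencies within named time windows.
* :func:`classify_trials` / :class:`TrialClassifier` — per-participant
  logistic-regression classification of trial condition from features,
  with stratified k-fold cross-validated accuracy and ROC AUC both from
  in-sample probabilities (labelled as such) and from held-out folds.
* behavioural indices — Cowan's K, inverse efficiency, RT filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .preprocess import EpochSet

__all__ = [
    "SignificanceRun",
    "ClassificationResult",
    "TrialClassifier",
    "lme_scan",
    "extract_features",
    "classify_trials",
    "permuted_chance_auc",
    "cowans_k",
    "inverse_efficiency",
    "rt_filter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignificanceRun:
    """Maximal stretch of consecutive samples with |t| above threshold."""

    start_s: float
    end_s: float
    factor: str
    min_duration_s: float = 0.2
    t_threshold: float = 2.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _code_binary(values: pd.Series, factor: str) -> np.ndarray:
    levels = sorted(values.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"factor '{factor}' must have exactly 2 levels, got {levels}")
    return (values.astype(str) == levels[1]).to_numpy(dtype=float)


def lme_scan(
    epoch_set: EpochSet,
    factors: list[str],
    min_run_s: float = 0.2,
    t_crit: float = 2.0,
    include_interaction: bool | None = None,
    participant_col: str = "participant",
) -> tuple[list[SignificanceRun], pd.DataFrame]:
    """Per-sample mixed-model scan over the epoch axis.

    At each sample a linear mixed model ``pupil ~ factors (+ interaction)``
    with by-participant random intercept and slopes for all fixed effects
    is fitted (REML, warm-started from the neighbouring sample).  Fixed
    effects with |t| > ``t_crit`` are collected into maximal runs; runs
    spanning fewer than ``min_run_s`` seconds are discarded.

    Returns ``(runs, table)`` where ``table`` holds one row per sample with
    the t-value of every term and a ``fallback`` flag marking samples where
    the full random structure failed and a random-intercept-only model was
    used instead.
    """
    meta = epoch_set.meta
    if participant_col not in meta.columns:
        raise ValueError(f"epoch metadata lacks a '{participant_col}' column")
    if len(meta[participant_col].unique()) < 2:
        raise ValueError("need >= 2 participants for a mixed model")
    if include_interaction is None:
        include_interaction = len(factors) == 2
    cols = [_code_binary(meta[f], f) for f in factors]
    terms = list(factors)
    if include_interaction and len(factors) == 2:
        cols.append(cols[0] * cols[1])
        terms.append(f"{factors[0]}:{factors[1]}")
    exog = np.column_stack([np.ones(len(meta))] + cols)
    groups = meta[participant_col].to_numpy()
    n_samples = epoch_set.times.size
    tvals = np.full((n_samples, len(terms)), np.nan)
    fallback = np.zeros(n_samples, dtype=bool)
    start = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*covariance (matrix )?is singular.*")
        for s in range(n_samples):
            y = epoch_set.data[:, s]
            res = None
            try:
                m = MixedLM(y, exog, groups=groups, exog_re=exog)
                res = m.fit(reml=True, method="lbfgs", maxiter=200, disp=False,
                            start_params=start)
                start = res.params_object
                if not np.all(np.isfinite(res.bse_fe)):
                    res = None
            except (np.linalg.LinAlgError, ValueError):
                res = None
            if res is None:
                fallback[s] = True
                start = None
                try:
                    m = MixedLM(y, exog, groups=groups,
                                exog_re=np.ones((len(y), 1)))
                    res = m.fit(reml=True, method="lbfgs", maxiter=200, disp=False)
                except (np.linalg.LinAlgError, ValueError):
                    continue
            t = res.fe_params / res.bse_fe
            tvals[s, :] = t[1:]
    table = pd.DataFrame(tvals, columns=terms)
    table.insert(0, "time_s", epoch_set.times)
    table["fallback"] = fallback
    if fallback.all():
        log.warning("all samples used the random-intercept-only fallback")
    dt = epoch_set.dt
    runs: list[SignificanceRun] = []
    for k, term in enumerate(terms):
        sig = np.abs(tvals[:, k]) > t_crit
        sig &= np.isfinite(tvals[:, k])
        idx = np.flatnonzero(np.diff(np.r_[0, sig.astype(int), 0]))
        for a, b in zip(idx[::2], idx[1::2]):
            n_run = b - a
            if n_run * dt >= min_run_s:
                runs.append(SignificanceRun(
                    start_s=float(epoch_set.times[a]),
                    end_s=float(epoch_set.times[b - 1] + dt),
                    factor=term, min_duration_s=min_run_s, t_threshold=t_crit))
    return runs, table


def extract_features(
    epoch_set: EpochSet,
    windows: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Signed extrema and earliest-sample latencies per named window.

    For each window ``name: (t0, t1)`` (seconds on the epoch axis) the
    output gains columns ``{name}_max_dil``, ``{name}_dil_lat_s``,
    ``{name}_max_con``, ``{name}_con_lat_s``.  Extrema are the signed
    maximum/minimum of the baselined trace; latencies are the earliest
    sample attaining the extremum.  Metadata columns are carried through.
    """
    t = epoch_set.times
    out = epoch_set.meta.copy().reset_index(drop=True)
    for name, (t0, t1) in windows.items():
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError(f"window '{name}' [{t0}, {t1}] outside the epoch span")
        mask = (t >= t0) & (t <= t1)
        seg = epoch_set.data[:, mask]
        tw = t[mask]
        i_max = np.argmax(seg, axis=1)
        i_min = np.argmin(seg, axis=1)
        out[f"{name}_max_dil"] = seg[np.arange(len(seg)), i_max]
        out[f"{name}_dil_lat_s"] = tw[i_max]
        out[f"{name}_max_con"] = seg[np.arange(len(seg)), i_min]
        out[f"{name}_con_lat_s"] = tw[i_min]
    return out


@dataclass
class ClassificationResult:
    """Per-participant logistic classification outcome.

    ``auc_insample`` follows the construction "ROC from the model's
    probabilities on all trials"; ``auc_cv`` uses pooled held-out fold
    probabilities and is the unbiased variant.  ``accuracy`` is always
    cross-validated.  The one-sample t-test compares participant
    accuracies against chance (0.5).
    """

    per_participant: pd.DataFrame
    mean_accuracy: float
    mean_auc_insample: float
    mean_auc_cv: float
    accuracy_t: float
    accuracy_p: float
    n_folds: int
    seed: int
    feature_names: list[str] = field(default_factory=list)
    excluded_participants: list = field(default_factory=list)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _fit_one_participant(X, y, n_folds, seed):
    """Returns (cv_accuracy, auc_insample, auc_cv)."""
    clf = LogisticRegression(max_iter=1000)
    clf.fit(X, y)
    p_in = clf.predict_proba(X)[:, 1]
    auc_in = roc_auc_score(y, p_in)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    p_out = np.zeros(len(y))
    for train, test in skf.split(X, y):
        f = LogisticRegression(max_iter=1000).fit(X[train], y[train])
        accs.append(float(np.mean(f.predict(X[test]) == y[test])))
        p_out[test] = f.predict_proba(X[test])[:, 1]
    return float(np.mean(accs)), float(auc_in), float(roc_auc_score(y, p_out))


def classify_trials(
    features: pd.DataFrame,
    label_col: str,
    feature_cols: list[str],
    participant_col: str = "participant",
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationResult:
    """Per-participant binary classification of trial condition.

    Features are z-scored within participant; folds are stratified by class
    within participant with the given seed.  Participants with a single
    class or fewer than ``n_folds`` trials per class are excluded with a
    warning.
    """
    rows, excluded = [], []
    for pid, grp in features.groupby(participant_col):
        y_lab = grp[label_col].astype(str)
        levels = sorted(y_lab.unique())
        if len(levels) != 2 or y_lab.value_counts().min() < n_folds:
            log.warning("participant %r excluded from classification", pid)
            excluded.append(pid)
            continue
        y = (y_lab == levels[1]).to_numpy(dtype=int)
        X = _standardize(grp[feature_cols].to_numpy(dtype=float))
        acc, auc_in, auc_cv = _fit_one_participant(X, y, n_folds, seed)
        rows.append({"participant": pid, "accuracy": acc,
                     "auc_insample": auc_in, "auc_cv": auc_cv,
                     "n_trials": len(y)})
    if not rows:
        raise ValueError("no participant had both classes represented")
    per = pd.DataFrame(rows)
    accs = per["accuracy"].to_numpy()
    if len(accs) > 1 and np.std(accs) > 0:
        t, p = sps.ttest_1samp(accs, 0.5)
    else:
        t, p = np.nan, np.nan
    return ClassificationResult(
        per_participant=per,
        mean_accuracy=float(accs.mean()),
        mean_auc_insample=float(per["auc_insample"].mean()),
        mean_auc_cv=float(per["auc_cv"].mean()),
        accuracy_t=float(t), accuracy_p=float(p),
        n_folds=n_folds, seed=seed, feature_names=list(feature_cols),
        excluded_participants=excluded,
    )


def permuted_chance_auc(
    features: pd.DataFrame,
    label_col: str,
    feature_cols: list[str],
    participant_col: str = "participant",
    n_permutations: int = 200,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Mean cross-validated AUC under within-participant label permutation.

    Returns one mean AUC (over participants) per permutation; the grand
    mean estimates the chance level (0.5 for a well-calibrated pipeline).
    """
    rng = np.random.default_rng(seed)
    groups = []
    for pid, grp in features.groupby(participant_col):
        y_lab = grp[label_col].astype(str)
        levels = sorted(y_lab.unique())
        if len(levels) != 2 or y_lab.value_counts().min() < n_folds:
            continue
        y = (y_lab == levels[1]).to_numpy(dtype=int)
        X = _standardize(grp[feature_cols].to_numpy(dtype=float))
        groups.append((X, y))
    if not groups:
        raise ValueError("no usable participants")
    out = np.zeros(n_permutations)
    for b in range(n_permutations):
        aucs = []
        for X, y in groups:
            yp = rng.permutation(y)
            if yp.min() == yp.max():  # cannot happen after the filter, but guard
                continue
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=int(rng.integers(2 ** 31 - 1)))
            p_out = np.zeros(len(yp))
            try:
                for train, test in skf.split(X, yp):
                    f = LogisticRegression(max_iter=1000).fit(X[train], yp[train])
                    p_out[test] = f.predict_proba(X[test])[:, 1]
                aucs.append(roc_auc_score(yp, p_out))
            except ValueError:
                continue
        out[b] = float(np.mean(aucs))
    return out


class TrialClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper around per-participant logistic classification.

    ``fit(X, y, participant=...)`` evaluates cross-validated accuracy and
    AUC per participant (attributes ``result_``, ``mean_accuracy_``,
    ``mean_auc_cv_``) and also fits a pooled logistic model used by
    ``predict``/``predict_proba`` on new feature matrices.
    """

    def __init__(self, n_folds: int = 5, seed: int = 0):
        self.n_folds = n_folds
        self.seed = seed

    def fit(self, X, y, participant=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if participant is None:
            participant = np.zeros(len(y), dtype=int)
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        df["label"] = y
        df["participant"] = np.asarray(participant)
        self.result_ = classify_trials(
            df, "label", [f"f{i}" for i in range(X.shape[1])],
            n_folds=self.n_folds, seed=self.seed)
        self.mean_accuracy_ = self.result_.mean_accuracy
        self.mean_auc_cv_ = self.result_.mean_auc_cv
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self._pooled = LogisticRegression(max_iter=1000).fit(_standardize(X), y_enc)
        self._pool_mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._pool_sd = sd
        return self

    def predict(self, X):
        X = (np.asarray(X, dtype=float) - self._pool_mu) / self._pool_sd
        return self.classes_[self._pooled.predict(X)]

    def predict_proba(self, X):
        X = (np.asarray(X, dtype=float) - self._pool_mu) / self._pool_sd
        return self._pooled.predict_proba(X)


# ---------------------------------------------------------------------------
# behavioural indices

def cowans_k(n_items: float, hit_rate: float, fa_rate: float) -> float:
    """Visual working memory capacity K = N * (hit rate - false-alarm rate)."""
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    return float(n_items) * (hit_rate - fa_rate)


def inverse_efficiency(mean_rt: float, prop_correct: float) -> float:
    """Inverse efficiency = mean correct RT / proportion correct.

    Units follow ``mean_rt`` (conventionally ms).  Lower is better; guards
    condition comparisons against speed-accuracy trade-offs.
    """
    if prop_correct <= 0:
        raise ValueError("inverse efficiency undefined for prop_correct <= 0")
    return mean_rt / prop_correct


def rt_filter(trials: pd.DataFrame, lo: float = 0.2, hi: float = 2.5,
              rt_col: str = "rt_s") -> pd.DataFrame:
    """Keep trials with lo <= RT <= hi (seconds); log the excluded fraction."""
    keep = (trials[rt_col] >= lo) & (trials[rt_col] <= hi)
    frac = 1.0 - keep.mean() if len(trials) else 0.0
    log.info("rt_filter excluded %.1f%% of trials", 100 * frac)
    return trials[keep]
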