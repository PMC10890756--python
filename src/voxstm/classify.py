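"""Before/after-deprivation classification of STM frames.

Protocol: PCA dimensionality reduction (250 components at the population
level; 30 at the participant level, fitted on all OTHER participants so
the target participant never contaminates the basis), an RBF-kernel SVM
tuned by grid search under stratified 5-fold inner cross-validation with
balanced accuracy as the criterion, and two outer cross-validation
schemes — 50x repeated 25% holdout, and leave-one-subject-out (LOSO,
population level only).  Split-level balanced accuracies are summarised
and tested against the 0.5 chance level with a two-sided one-sample
t-test.  Note that repeated holdout splits share training data, so this
t-test is the protocol's own convention rather than an exact test; the
repeated splits are not independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SplitPlan",
    "RunResult",
    "split_dataset",
    "fit_reducer",
    "RbfSvmClassifier",
    "balanced_accuracy",
    "rau",
    "evaluate_population",
    "evaluate_participants",
    "within_across",
]

POPULATION_COMPONENTS = 250
PARTICIPANT_COMPONENTS = 30
DEFAULT_C = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_FACTORS = (0.1, 1.0, 10.0)


@dataclass(frozen=True)
class SplitPlan:
    """Outer cross-validation plan."""

    strategy: str = "holdout_repeated"  # or "loso"
    n_repeats: int = 50
    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("holdout_repeated", "loso"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def split_dataset(labels, participants, plan: SplitPlan, level: str = "population"):
    """Train/test index pairs under the plan.

    ``holdout_repeated`` draws `n_repeats` independent class-stratified
    splits holding out `test_fraction` of the frames; ``loso`` yields one
    split per participant whose test set is all of that participant's
    frames.  LOSO at the participant level is rejected: with a single
    subject there is no one to leave out.
    """
    labels = np.asarray(labels)
    participants = np.asarray(participants)
    if labels.shape[0] != participants.shape[0]:
        raise ValueError("labels and participants must align")
    if labels.shape[0] < 8:
        raise ValueError("need at least 8 frames to split")
    if plan.strategy == "loso":
        if level == "participant":
            raise ValueError("LOSO is undefined at the participant level")
        uniq = np.unique(participants)
        if uniq.size < 2:
            raise ValueError("LOSO needs at least 2 participants")
        splits = []
        for p in uniq:
            test = np.flatnonzero(participants == p)
            train = np.flatnonzero(participants != p)
            splits.append((train, test))
        return splits
    sss = StratifiedShuffleSplit(
        n_splits=plan.n_repeats, test_size=plan.test_fraction, random_state=plan.seed
    )
    return [(tr.copy(), te.copy()) for tr, te in sss.split(np.zeros_like(labels), labels)]


def fit_reducer(train_features, n_components: int, random_state: int | None = 0) -> PCA:
    """Fit the PCA feature reducer on training data only.

    At the population level the default is 250 components; at the
    participant level 30 components fitted on all other participants'
    frames (call with those frames).
    """
    X = np.asarray(train_features, dtype=float)
    max_comp = min(X.shape)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=random_state)
    pca.fit(X)
    return pca


class RbfSvmClassifier(ClassifierMixin, BaseEstimator):
    """PCA + grid-searched RBF-SVM frame classifier.

    Parameters
    ----------
    n_components:
        PCA dimensionality when the reducer is fitted internally.
    reducer:
        ``None`` (fit a PCA of `n_components` on the training frames) or a
        pre-fitted PCA — used when the basis must come from other data,
        e.g. the participant-level protocol where it is fitted on all
        other participants.
    C_values, gamma_factors:
        Hyperparameter grid; the RBF width grid is ``gamma_factors / d``
        with ``d`` the reduced dimensionality.
    cv_folds:
        Inner stratified folds for the grid search (balanced accuracy).
    pos_label:
        The label treated as the "after deprivation" class (positive mask
        sign downstream).

    Attributes (after fit)
    ----------------------
    reducer_ : fitted PCA; svm_ : fitted SVC; best_params_ : chosen grid
    point; train_sd_ : per-component SD of the reduced training frames
    (used to scale interpretation probes); classes_.
    """

    def __init__(
        self,
        n_components: int = PARTICIPANT_COMPONENTS,
        reducer=None,
        C_values: tuple = DEFAULT_C,
        gamma_factors: tuple = DEFAULT_GAMMA_FACTORS,
        cv_folds: int = 5,
        pos_label="after",
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.reducer = reducer
        self.C_values = C_values
        self.gamma_factors = gamma_factors
        self.cv_folds = cv_folds
        self.pos_label = pos_label
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes in training labels, got {classes.size}")
        self.classes_ = classes
        if self.reducer is not None:
            self.reducer_ = self.reducer  # pre-fitted basis (never refit here)
        else:
            self.reducer_ = fit_reducer(X, self.n_components, random_state=self.random_state)
        Z = self.reducer_.transform(X)
        d = Z.shape[1]
        grid = {
            "C": list(self.C_values),
            "gamma": [g / d for g in self.gamma_factors],
        }
        folds = min(self.cv_folds, int(np.min(np.bincount(np.searchsorted(classes, y)))))
        if folds < 2:
            # Too few per-class samples for an inner CV: fall back to mid-grid.
            best = {"C": 1.0, "gamma": 1.0 / d}
        else:
            # Plain loop rather than GridSearchCV: identical protocol
            # (stratified folds, balanced accuracy, first-best tie-break)
            # with far less overhead on the many tiny fits this pipeline runs.
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.random_state)
            y_bin = y == classes[1]
            fold_idx = list(skf.split(Z, y_bin))
            best, best_score = None, -np.inf
            for C in grid["C"]:
                for gamma in grid["gamma"]:
                    scores = []
                    for tr, te in fold_idx:
                        m = SVC(kernel="rbf", C=C, gamma=gamma).fit(Z[tr], y_bin[tr])
                        pred = m.predict(Z[te])
                        true = y_bin[te]
                        sens = np.mean(pred[true]) if true.any() else 0.0
                        spec_ = np.mean(~pred[~true]) if (~true).any() else 0.0
                        scores.append(0.5 * (sens + spec_))
                    score = float(np.mean(scores))
                    if score > best_score:
                        best, best_score = {"C": C, "gamma": gamma}, score
        self.best_params_ = dict(best)
        self.svm_ = SVC(kernel="rbf", **best).fit(Z, y)
        self.train_sd_ = Z.std(axis=0, ddof=1)
        return self

    def transform_reduced(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.reducer_.transform(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.svm_.predict(self.transform_reduced(X))

    def predict_reduced(self, Z):
        """Predict directly in the reduced space (used by probe analyses)."""
        check_is_fitted(self, "svm_")
        return self.svm_.predict(np.asarray(Z, dtype=float))

    def decision_function(self, X):
        return self.svm_.decision_function(self.transform_reduced(X))

    def score(self, X, y):
        return balanced_accuracy(y, self.predict(X))


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of sensitivity and specificity; 0.5 is chance for two classes."""
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise ValueError("balanced accuracy undefined with a single true class")
    return float(balanced_accuracy_score(y_true, y_pred))


def rau(p):
    """Rationalized arcsine transform of a proportion (Studebaker).

    ``RAU = (146 / pi) * 2 * arcsin(sqrt(p)) - 23``; maps [0, 1] onto
    [-23, 123] with RAU(0.5) = 50, approximately linear mid-range and
    variance-stabilising near the endpoints.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = (146.0 / np.pi) * 2.0 * np.arcsin(np.sqrt(p)) - 23.0
    return float(out) if out.ndim == 0 else out


@dataclass
class RunResult:
    """Per-split balanced accuracies and their test against chance."""

    baccs: np.ndarray
    level: str  # "population" | "participant"
    strategy: str
    participant: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.baccs))

    @property
    def sd(self) -> float:
        return float(np.std(self.baccs, ddof=1)) if len(self.baccs) > 1 else 0.0

    @property
    def t_stat(self) -> float:
        return self._ttest()[0]

    @property
    def p_value(self) -> float:
        return self._ttest()[1]

    def _ttest(self):
        if len(self.baccs) < 2 or self.sd == 0.0:
            return (np.nan, np.nan)
        t, p = stats.ttest_1samp(self.baccs, 0.5)
        return (float(t), float(p))


def _audit_disjoint(train, test):
    if np.intersect1d(train, test).size:
        raise AssertionError("train/test overlap: protocol leakage")


def evaluate_population(
    X,
    y,
    participants,
    plan: SplitPlan | None = None,
    n_components: int = POPULATION_COMPONENTS,
    reducer_on_all: bool = False,
    clf_kwargs: dict | None = None,
) -> RunResult:
    """Population-level evaluation under repeated holdout or LOSO.

    By default the PCA is refitted on each split's training frames; the
    ``reducer_on_all`` switch reproduces the alternative reading in which
    one basis is fitted on the whole dataset (optimistic; off by default).
    """
    plan = plan or SplitPlan()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    clf_kwargs = dict(clf_kwargs or {})
    clf_kwargs.setdefault("random_state", plan.seed)
    splits = split_dataset(y, participants, plan, level="population")
    shared = (
        fit_reducer(X, min(n_components, min(X.shape)), random_state=plan.seed)
        if reducer_on_all
        else None
    )
    baccs = []
    for train, test in splits:
        _audit_disjoint(train, test)
        ncomp = min(n_components, len(train), X.shape[1])
        clf = RbfSvmClassifier(n_components=ncomp, reducer=shared, **clf_kwargs)
        clf.fit(X[train], y[train])
        baccs.append(balanced_accuracy(y[test], clf.predict(X[test])))
    return RunResult(np.asarray(baccs), level="population", strategy=plan.strategy)


@dataclass
class ParticipantEvaluation:
    participant: int
    result: RunResult
    models: list = field(default_factory=list)
    frame_index: np.ndarray | None = None


def evaluate_participants(
    X,
    y,
    participants,
    n_repeats: int = 50,
    test_fraction: float = 0.25,
    n_components: int = PARTICIPANT_COMPONENTS,
    seed: int = 0,
    keep_models: bool = False,
    clf_kwargs: dict | None = None,
) -> list[ParticipantEvaluation]:
    """Per-participant evaluation with a leakage-safe reducer.

    For each participant the PCA basis is fitted on all OTHER
    participants' frames, then `n_repeats` stratified 25% holdout splits
    of the participant's own frames are classified.  With
    ``keep_models=True`` the fitted per-split classifiers are retained for
    reverse-correlation interpretation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    participants = np.asarray(participants)
    clf_kwargs = dict(clf_kwargs or {})
    out = []
    for p in np.unique(participants):
        own = np.flatnonzero(participants == p)
        others = np.flatnonzero(participants != p)
        if np.intersect1d(own, others).size:
            raise AssertionError("reducer audit failed: target frames in basis fit")
        ncomp = min(n_components, len(others), X.shape[1])
        reducer = fit_reducer(X[others], ncomp, random_state=seed)
        plan = SplitPlan(
            strategy="holdout_repeated",
            n_repeats=n_repeats,
            test_fraction=test_fraction,
            seed=seed + int(p),
        )
        splits = split_dataset(y[own], participants[own], plan, level="population")
        baccs, models = [], []
        for train, test in splits:
            _audit_disjoint(train, test)
            clf = RbfSvmClassifier(
                reducer=reducer, random_state=plan.seed, **clf_kwargs
            )
            clf.fit(X[own[train]], y[own[train]])
            baccs.append(balanced_accuracy(y[own[test]], clf.predict(X[own[test]])))
            if keep_models:
                models.append(clf)
        out.append(
            ParticipantEvaluation(
                participant=int(p),
                result=RunResult(
                    np.asarray(baccs),
                    level="participant",
                    strategy="holdout_repeated",
                    participant=int(p),
                ),
                models=models,
                frame_index=own,
            )
        )
    return out


@dataclass
class WithinAcrossResult:
    """Within-state vs across-state session discriminability (RAU units)."""

    per_participant: "object"  # DataFrame: participant, within_rau, across_rau
    t_stat: float
    p_value: float
    skipped: list = field(default_factory=list)


def within_across(
    X,
    session_index,
    participants,
    n_sessions_per_state: int = 3,
    n_repeats: int = 10,
    test_fraction: float = 0.25,
    n_components: int = PARTICIPANT_COMPONENTS,
    seed: int = 0,
    clf_kwargs: dict | None = None,
) -> WithinAcrossResult:
    """Control analysis: can sessions be told apart within a state?

    For every participant and every unordered pair of sessions (with 3+3
    sessions: 6 "within"-state pairs, 9 "across"-state pairs) a classifier
    is trained to discriminate the two sessions, using the participant-
    level reducer (fitted on other participants).  Pair accuracies are
    averaged within each group, converted to rationalized arcsine units,
    and compared with a paired two-tailed t-test across participants.  A
    genuine deprivation effect shows up as across > within.
    """
    import itertools

    import pandas as pd

    X = np.asarray(X, dtype=float)
    session_index = np.asarray(session_index)
    participants = np.asarray(participants)
    clf_kwargs = dict(clf_kwargs or {})
    rows, skipped = [], []
    for p in np.unique(participants):
        own = np.flatnonzero(participants == p)
        sessions = np.unique(session_index[own])
        if sessions.size != 2 * n_sessions_per_state:
            skipped.append(int(p))
            warnings.warn(f"participant {p} missing sessions; skipped", RuntimeWarning)
            continue
        others = np.flatnonzero(participants != p)
        ncomp = min(n_components, len(others), X.shape[1])
        reducer = fit_reducer(X[others], ncomp, random_state=seed)
        within_accs, across_accs = [], []
        for sa, sb in itertools.combinations(sessions, 2):
            state_a = sa <= n_sessions_per_state
            state_b = sb <= n_sessions_per_state
            idx = own[np.isin(session_index[own], [sa, sb])]
            yp = session_index[idx]
            pair_seed = seed + 31 * int(p) + int(sa * 7 + sb)
            # Session pairs can be as small as a handful of frames; hold
            # out at least one frame of each session per split.
            n_test = max(2, int(round(test_fraction * len(idx))))
            sss = StratifiedShuffleSplit(
                n_splits=n_repeats, test_size=n_test, random_state=pair_seed
            )
            accs = []
            for train, test in sss.split(np.zeros_like(yp), yp):
                _audit_disjoint(train, test)
                clf = RbfSvmClassifier(reducer=reducer, random_state=pair_seed, **clf_kwargs)
                clf.fit(X[idx[train]], yp[train])
                accs.append(balanced_accuracy(yp[test], clf.predict(X[idx[test]])))
            (within_accs if state_a == state_b else across_accs).append(np.mean(accs))
        rows.append(
            {
                "participant": int(p),
                "n_within_pairs": len(within_accs),
                "n_across_pairs": len(across_accs),
                "within_bacc": float(np.mean(within_accs)),
                "across_bacc": float(np.mean(across_accs)),
                "within_rau": rau(np.mean(within_accs)),
                "across_rau": rau(np.mean(across_accs)),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        t, pval = stats.ttest_rel(df["across_rau"], df["within_rau"])
    else:
        t, pval = np.nan, np.nan
    return WithinAcrossResult(df, float(t), float(pval), skipped)
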