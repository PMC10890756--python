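"""Classification protocol: splits, leakage rules, BAcc, RAU, controls."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voxstm.classify import (
    RbfSvmClassifier,
    SplitPlan,
    balanced_accuracy,
    evaluate_participants,
    fit_reducer,
    rau,
    split_dataset,
    within_across,
)


def _toy_labels(n=40, n_participants=4):
    labels = np.array(["before", "after"] * (n // 2))
    participants = np.repeat(np.arange(n_participants), n // n_participants)
    return labels, participants


# ---- splits --------------------------------------------------------------


def test_holdout_splits_count_fraction_disjoint():
    labels, parts = _toy_labels()
    plan = SplitPlan("holdout_repeated", n_repeats=50, test_fraction=0.25, seed=1)
    splits = split_dataset(labels, parts, plan)
    assert len(splits) == 50
    for train, test in splits:
        assert len(test) == 10
        assert np.intersect1d(train, test).size == 0
        # class stratification
        assert set(labels[test]) == {"before", "after"}


def test_split_determinism_and_variation():
    labels, parts = _toy_labels()
    plan = SplitPlan(seed=3)
    a = split_dataset(labels, parts, plan)
    b = split_dataset(labels, parts, plan)
    assert all(np.array_equal(x[1], y[1]) for x, y in zip(a, b))
    c = split_dataset(labels, parts, SplitPlan(seed=4))
    assert any(not np.array_equal(x[1], y[1]) for x, y in zip(a, c))


def test_loso_one_split_per_participant():
    labels, parts = _toy_labels(n=40, n_participants=5)
    splits = split_dataset(labels, parts, SplitPlan("loso"))
    assert len(splits) == 5
    for train, test in splits:
        assert np.unique(parts[test]).size == 1
        assert np.intersect1d(train, test).size == 0


def test_loso_rejected_at_participant_level():
    labels, parts = _toy_labels()
    with pytest.raises(ValueError, match="participant level"):
        split_dataset(labels, parts, SplitPlan("loso"), level="participant")


@pytest.mark.parametrize("kwargs", [{"test_fraction": 0.0}, {"strategy": "bootstrap"},
                                    {"n_repeats": 0}])
def test_invalid_split_plan(kwargs):
    with pytest.raises(ValueError):
        SplitPlan(**kwargs)


# ---- reducer -------------------------------------------------------------


def test_reducer_projection_identity_and_errors(rng):
    X = rng.standard_normal((30, 10))
    pca = fit_reducer(X, 5)
    v = pca.components_[0] * 2.0 + pca.mean_
    rec = pca.inverse_transform(pca.transform(v[None, :]))[0]
    assert np.allclose(rec, v, atol=1e-8)  # in-span vectors reconstruct exactly
    with pytest.raises(ValueError, match="n_components"):
        fit_reducer(X, 11)


# ---- balanced accuracy and RAU -------------------------------------------


def test_balanced_accuracy_cases():
    y = np.array(["after"] * 5 + ["before"] * 5)
    assert balanced_accuracy(y, y) == 1.0
    assert balanced_accuracy(y, np.array(["after"] * 10)) == 0.5
    # sensitivity 0.8, specificity 0.6 -> 0.7
    pred = np.array(["after"] * 4 + ["before"] + ["before"] * 3 + ["after"] * 2)
    assert balanced_accuracy(y, pred) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        balanced_accuracy(np.array(["after"] * 4), np.array(["after"] * 4))


def test_rau_closed_forms_and_bounds():
    assert rau(0.5) == pytest.approx(50.0)
    assert rau(1.0) == pytest.approx(123.0)
    assert rau(0.0) == pytest.approx(-23.0)
    with pytest.raises(ValueError):
        rau(1.2)


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_rau_strictly_increasing(p, q):
    if p < q:
        assert rau(p) < rau(q)
    elif p == q:
        assert rau(p) == rau(q)


# ---- classifier ----------------------------------------------------------


def _separable(rng, n=40, d=8, gap=6.0):
    X = rng.standard_normal((n, d))
    y = np.array(["before", "after"] * (n // 2))
    X[y == "after", 0] += gap
    return X, y


def test_separable_training_bacc_is_one(rng):
    X, y = _separable(rng)
    clf = RbfSvmClassifier(n_components=4, random_state=0).fit(X, y)
    assert balanced_accuracy(y, clf.predict(X)) == 1.0
    assert clf.best_params_["C"] in (0.1, 1.0, 10.0, 100.0)


def test_classifier_deterministic(rng):
    X, y = _separable(rng)
    a = RbfSvmClassifier(n_components=4, random_state=7).fit(X, y)
    b = RbfSvmClassifier(n_components=4, random_state=7).fit(X, y)
    assert a.best_params_ == b.best_params_
    assert np.array_equal(a.predict(X), b.predict(X))


def test_single_class_training_raises(rng):
    X = rng.standard_normal((10, 4))
    with pytest.raises(ValueError, match="classes"):
        RbfSvmClassifier(n_components=2).fit(X, np.array(["after"] * 10))


def test_permuted_labels_give_chance_accuracy(rng):
    """Monte-Carlo null: with random labels the classifier works at chance."""
    baccs = []
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = r.standard_normal((120, 10))
        y = np.array(["before", "after"] * 60)
        train, test = np.arange(0, 90), np.arange(90, 120)
        clf = RbfSvmClassifier(n_components=5, random_state=seed).fit(X[train], y[train])
        baccs.append(balanced_accuracy(y[test], clf.predict(X[test])))
    assert abs(np.mean(baccs) - 0.5) < 0.1


def test_label_permutation_audit(rng):
    """BAcc of fixed predictions against permuted labels converges to 0.5."""
    y = np.array(["before", "after"] * 30)
    pred = np.array(["before"] * 30 + ["after"] * 30)
    baccs = []
    for _ in range(200):
        baccs.append(balanced_accuracy(rng.permutation(y), pred))
    se = np.std(baccs, ddof=1) / np.sqrt(len(baccs))
    assert abs(np.mean(baccs) - 0.5) < 3 * se + 1e-9


# ---- participant-level evaluation ----------------------------------------


def test_participant_reducer_never_sees_target(rng):
    """Leakage audit: the target participant's frames do not move the basis.

    Corrupting one participant's frames must leave every OTHER
    participant's reducer unchanged only if the target participant was
    excluded; we check the direct consequence — the target's own
    evaluation changes, others' reducers (fitted without them) change
    only through the corrupted participant's inclusion in their basis.
    """
    X = rng.standard_normal((48, 12))
    y = np.tile(["before", "after"], 24)
    parts = np.repeat([1, 2, 3, 4], 12)
    evs = evaluate_participants(X, y, parts, n_repeats=4, n_components=4, seed=0,
                                keep_models=True)
    # reducer attached to participant 1's models was fitted on others:
    # projecting participant-1 frames through it and through a PCA fitted
    # WITH participant 1 must differ
    red = evs[0].models[0].reducer_
    with_target = fit_reducer(X, 4)
    assert not np.allclose(np.abs(red.components_), np.abs(with_target.components_))


def test_participant_evaluation_structure(rng):
    X = rng.standard_normal((48, 12))
    y = np.tile(["before", "after"], 24)
    parts = np.repeat([1, 2, 3, 4], 12)
    evs = evaluate_participants(X, y, parts, n_repeats=6, n_components=4, seed=0)
    assert [e.participant for e in evs] == [1, 2, 3, 4]
    for e in evs:
        assert len(e.result.baccs) == 6
        assert np.all((e.result.baccs >= 0) & (e.result.baccs <= 1))
        assert e.result.level == "participant"


# ---- within/across control ------------------------------------------------


def test_within_across_enumeration_and_effect(rng):
    """3+3 sessions give 6 within and 9 across pairs; a planted state
    shift makes across-RAU exceed within-RAU."""
    n_part, frames_per_sess = 6, 4
    X, sess, parts = [], [], []
    for p in range(n_part):
        for s in range(1, 7):
            f = rng.standard_normal((frames_per_sess, 10))
            if s >= 4:
                f[:, 0] += 4.0  # across-state shift only
            X.append(f)
            sess.extend([s] * frames_per_sess)
            parts.extend([p] * frames_per_sess)
    X = np.vstack(X)
    res = within_across(X, np.array(sess), np.array(parts), n_repeats=4,
                        n_components=5, seed=0)
    df = res.per_participant
    assert (df.n_within_pairs == 6).all()
    assert (df.n_across_pairs == 9).all()
    assert (df.across_rau > df.within_rau).all()
    assert res.p_value < 0.05
    assert res.t_stat > 0
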