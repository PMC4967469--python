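from itertools import combinations, combinations_with_replacement, product

import numpy as np
import pandas as pd
import pytest

import pharmacoscape as ps
from pharmacoscape.logic import (
    DEFAULT_COMPLEXITIES,
    LogicFormula,
    binarize_and_weight,
    cross_validate,
    evaluate_formula,
    feature_importance,
    fit_logic_model,
    model_metrics,
    permutation_significance,
)


# -- independent oracles ----------------------------------------------------

def naive_eval(formula, row):
    """Direct truth-table evaluation of one sample (dict feature -> 0/1)."""
    clause_vals = []
    for clause in formula.clauses:
        lits = [(row[f] == 0) if neg else (row[f] == 1) for f, neg in clause]
        clause_vals.append(all(lits) if formula.form == "dnf" else any(lits))
    return any(clause_vals) if formula.form == "dnf" else all(clause_vals)


def naive_best_objective(X, labels, weights, k, m, form="dnf",
                         min_specificity=0.8):
    """Exhaustive search over every K-clause M-literal formula by direct
    evaluation; returns the minimal feasible weighted error (inf if none)."""
    features = list(X.columns)
    clauses = [
        tuple((f, neg) for f, neg in zip(feats, negs))
        for feats in combinations(features, m)
        for negs in product([False, True], repeat=m)
    ]
    n_neg = int((~labels).sum())
    best = np.inf
    rows = X.to_dict(orient="records")
    for combo in combinations_with_replacement(clauses, k):
        formula = LogicFormula(tuple(combo), form=form)
        pred = np.array([naive_eval(formula, r) for r in rows])
        fp = int((pred & ~labels).sum())
        if n_neg and (n_neg - fp) / n_neg < min_specificity:
            continue
        err = float(weights[pred != labels].sum())
        best = min(best, err)
    return best


def random_instance(rng, n, f):
    X = pd.DataFrame((rng.random((n, f)) < rng.uniform(0.2, 0.5)).astype(float),
                     columns=[f"F{j}" for j in range(f)])
    ic50 = rng.normal(0, 1, n)
    theta = float(np.quantile(ic50, rng.uniform(0.2, 0.5)))
    labels, weights = binarize_and_weight(ic50, theta)
    return X, labels, weights


# -- binarization and weighting ---------------------------------------------

def test_weights_sum_to_half_per_class():
    rng = np.random.default_rng(0)
    for _ in range(20):
        ic50 = rng.normal(0, 2, 50)
        theta = float(np.quantile(ic50, 0.3))
        labels, weights = binarize_and_weight(ic50, theta)
        assert weights[labels].sum() == pytest.approx(0.5, abs=1e-12)
        assert weights[~labels].sum() == pytest.approx(0.5, abs=1e-12)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=4,
                    max_size=60),
           st.floats(min_value=-5, max_value=5))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_weight_conservation_holds_for_any_input(ic50, theta):
        ic50 = np.asarray(ic50)
        if (ic50 <= theta).all() or (ic50 > theta).all():
            return  # one class empty: out of contract
        labels, weights = binarize_and_weight(ic50, theta)
        assert weights[labels].sum() == pytest.approx(0.5, abs=1e-9)
        assert weights[~labels].sum() == pytest.approx(0.5, abs=1e-9)
        assert (weights >= 0).all()
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_sample_exactly_at_threshold_has_zero_weight():
    labels, weights = binarize_and_weight([0.0, -1.0, 1.0, 2.0], 0.0)
    assert labels[0]  # ic50 == theta counts as sensitive
    assert weights[0] == 0.0


def test_one_class_empty_raises():
    with pytest.raises(ValueError, match="non-empty"):
        binarize_and_weight([1.0, 2.0, 3.0], 0.0)


# -- formula evaluation -----------------------------------------------------

def test_single_literal_equals_feature_column():
    X = pd.DataFrame({"A": [1.0, 0.0, 1.0], "B": [0.0, 0.0, 1.0]})
    f = LogicFormula(((("A", False),),), "dnf")
    assert list(evaluate_formula(f, X)) == [1.0, 0.0, 1.0]


def test_or_formula_truth_table():
    X = pd.DataFrame({"A": [1.0], "B": [0.0]})
    f = LogicFormula(((("A", False),), (("B", False),)), "dnf")
    assert evaluate_formula(f, X)[0] == 1.0


def test_missing_feature_value_excludes_sample():
    X = pd.DataFrame({"A": [1.0, np.nan]})
    f = LogicFormula(((("A", False),),), "dnf")
    out = evaluate_formula(f, X)
    assert out[0] == 1.0 and np.isnan(out[1])


def test_unknown_feature_raises():
    with pytest.raises(KeyError, match="unknown features"):
        evaluate_formula(LogicFormula(((("Z", False),),), "dnf"),
                         pd.DataFrame({"A": [1.0]}))


@pytest.mark.parametrize("form", ["dnf", "cnf"])
def test_random_formulas_match_truth_table_oracle(form):
    rng = np.random.default_rng(1)
    features = ["A", "B", "C", "D"]
    all_rows = pd.DataFrame(list(product([0.0, 1.0], repeat=4)),
                            columns=features)
    for _ in range(50):
        k = int(rng.integers(1, 3))
        clauses = []
        for _ in range(k):
            m = int(rng.integers(1, 3))
            feats = rng.choice(features, size=m, replace=False)
            clauses.append(tuple(
                (f, bool(rng.integers(2))) for f in feats))
        formula = LogicFormula(tuple(clauses), form)
        got = evaluate_formula(formula, all_rows)
        expected = [naive_eval(formula, r)
                    for r in all_rows.to_dict(orient="records")]
        assert list(got == 1.0) == expected


# -- optimizer --------------------------------------------------------------

def test_perfect_single_feature_recovered_with_zero_error():
    rng = np.random.default_rng(2)
    X = pd.DataFrame((rng.random((40, 5)) < 0.4).astype(float),
                     columns=list("ABCDE"))
    labels = X["C"].to_numpy() == 1.0
    if labels.sum() < 5:  # ensure enough sensitive samples
        labels[:5] = True
        X.iloc[:5, 2] = 1.0
    weights = np.full(len(labels), 0.0)
    weights[labels] = 0.5 / labels.sum()
    weights[~labels] = 0.5 / (~labels).sum()
    model = fit_logic_model(X, labels, weights, (1, 1))
    assert str(model.formula) == "C"
    assert model.train_error == pytest.approx(0.0, abs=1e-12)


def test_random_labels_yield_specificity_constrained_model():
    rng = np.random.default_rng(3)
    X = pd.DataFrame((rng.random((60, 6)) < 0.3).astype(float),
                     columns=[f"F{j}" for j in range(6)])
    ic50 = rng.normal(0, 1, 60)
    labels, weights = binarize_and_weight(ic50, float(np.quantile(ic50, 0.3)))
    for c in DEFAULT_COMPLEXITIES:
        model = fit_logic_model(X, labels, weights, c)
        if model.formula is not None:
            assert model.specificity >= 0.8


@pytest.mark.parametrize("seed", range(8))
def test_optimizer_matches_exhaustive_oracle_small_instances(seed):
    rng = np.random.default_rng(100 + seed)
    X, labels, weights = random_instance(rng, n=25, f=5)
    if labels.sum() < 5:
        pytest.skip("instance lacks sensitive samples")
    for (k, m) in [(1, 1), (2, 1), (1, 2), (2, 2)]:
        model = fit_logic_model(X, labels, weights, (k, m), prefilter=None)
        oracle = naive_best_objective(X, labels, weights, k, m)
        if model.formula is None:
            assert np.isinf(oracle)
        else:
            assert model.train_error == pytest.approx(oracle, abs=1e-10)


def test_cnf_optimizer_matches_oracle():
    rng = np.random.default_rng(42)
    X, labels, weights = random_instance(rng, n=25, f=4)
    if labels.sum() < 5:
        labels[:5] = True
    model = fit_logic_model(X, labels, weights, (2, 2), form="cnf",
                            prefilter=None, min_sensitive=1)
    oracle = naive_best_objective(X, labels, weights, 2, 2, form="cnf")
    if model.formula is None:
        assert np.isinf(oracle)
    else:
        assert model.train_error == pytest.approx(oracle, abs=1e-10)


def test_objective_is_nested_across_complexities():
    rng = np.random.default_rng(4)
    X, labels, weights = random_instance(rng, n=40, f=6)
    if labels.sum() < 5:
        pytest.skip("instance lacks sensitive samples")
    base = fit_logic_model(X, labels, weights, (1, 1)).train_error
    for c in DEFAULT_COMPLEXITIES[1:]:
        model = fit_logic_model(X, labels, weights, c)
        if model.formula is not None:
            assert model.train_error <= base + 1e-10


def test_feature_cap_respected():
    rng = np.random.default_rng(5)
    X, labels, weights = random_instance(rng, n=50, f=8)
    if labels.sum() < 5:
        pytest.skip("instance lacks sensitive samples")
    for c in DEFAULT_COMPLEXITIES:
        model = fit_logic_model(X, labels, weights, c)
        assert len(model.features) <= 4


# -- cross-validation and permutation ---------------------------------------

def test_noiseless_single_feature_selects_simplest_complexity():
    rng = np.random.default_rng(6)
    X = pd.DataFrame((rng.random((100, 4)) < 0.3).astype(float),
                     columns=list("ABCD"))
    ic50 = np.where(X["A"] == 1.0, -2.0, 2.0) + rng.normal(0, 1e-6, 100)
    res = cross_validate(X, ic50, theta=0.0, repeats=2, seed=0)
    assert res.selected_complexity == (1, 1)
    assert str(res.model.formula) == "A"
    assert res.cv_error == pytest.approx(0.0, abs=1e-9)


def test_cross_validation_is_deterministic():
    rng = np.random.default_rng(7)
    X = pd.DataFrame((rng.random((80, 5)) < 0.3).astype(float),
                     columns=list("ABCDE"))
    ic50 = rng.normal(0, 1, 80) - 1.5 * X["B"].to_numpy()
    r1 = cross_validate(X, ic50, theta=0.0, repeats=2, seed=3)
    r2 = cross_validate(X, ic50, theta=0.0, repeats=2, seed=3)
    assert r1.selected_complexity == r2.selected_complexity
    pd.testing.assert_series_equal(r1.cv_errors, r2.cv_errors)
    assert str(r1.model.formula) == str(r2.model.formula)


def test_permutation_p_value_bounds_and_signal():
    rng = np.random.default_rng(8)
    X = pd.DataFrame((rng.random((120, 4)) < 0.3).astype(float),
                     columns=list("ABCD"))
    ic50 = rng.normal(0, 0.4, 120) - 3.0 * X["A"].to_numpy()
    res = cross_validate(X, ic50, theta=-1.0, repeats=1, seed=0)
    p = permutation_significance(res, X, ic50, theta=-1.0, n_perm=19,
                                 seed=0, repeats=1)
    assert 1 / 20 <= p <= 1.0
    assert p == pytest.approx(0.05)  # strong signal beats every permutation
    with pytest.raises(ValueError, match="19"):
        permutation_significance(res, X, ic50, theta=-1.0, n_perm=5)


# -- metrics and importance -------------------------------------------------

def test_recall_of_partial_model_from_counts():
    """A model capturing 10 of 22 sensitive lines has ~45% recall."""
    labels = np.zeros(60, dtype=bool)
    labels[:22] = True
    X = pd.DataFrame({"A": np.zeros(60)})
    X.iloc[:10, 0] = 1.0  # model fires on 10 truly sensitive lines
    model = ps.LogicModel(LogicFormula(((("A", False),),), "dnf"), 0.0, 0.0)
    precision, recall, specificity = model_metrics(model, X, labels)
    assert recall == pytest.approx(10 / 22)
    assert round(100 * recall) == 45
    assert precision == 1.0 and specificity == 1.0


def test_perfect_and_null_model_metrics():
    labels = np.array([True] * 5 + [False] * 5)
    X = pd.DataFrame({"A": labels.astype(float)})
    perfect = ps.LogicModel(LogicFormula(((("A", False),),), "dnf"), 0.0, 0.0)
    assert model_metrics(perfect, X, labels) == (1.0, 1.0, 1.0)
    null = ps.LogicModel(None, 0.0, 0.5, feasible=False)
    precision, recall, specificity = model_metrics(null, X, labels)
    assert recall == 0.0 and specificity == 1.0 and precision is None


def test_feature_importance_concentration_and_conservation():
    rng = np.random.default_rng(9)
    X = pd.DataFrame((rng.random((100, 4)) < 0.3).astype(float),
                     columns=list("ABCD"))
    ic50 = np.where(X["A"] == 1.0, -2.0, 2.0) + rng.normal(0, 0.1, 100)
    res = cross_validate(X, ic50, theta=0.0, repeats=1, seed=0)
    per_feature, per_class = feature_importance(
        {"drug": res}, classes={"A": "CG", "B": "CG", "C": "RACS_amp",
                                "D": "iCpG"})
    assert per_feature.idxmax() == "A"
    assert per_feature.sum() == pytest.approx(1.0)
    assert per_class.sum() == pytest.approx(1.0)
    assert "B" not in per_feature.index or per_feature["B"] < 0.2


def test_estimator_interface_round_trip():
    rng = np.random.default_rng(10)
    X = pd.DataFrame((rng.random((100, 5)) < 0.3).astype(float),
                     columns=list("ABCDE"))
    ic50 = rng.normal(0, 0.5, 100) - 3.0 * X["D"].to_numpy()
    est = ps.LogicModelCV(theta=-1.0, repeats=1, random_state=0)
    est.fit(X, ic50)
    assert "D" in est.model_.features
    pred = est.predict(X)
    assert pred.dtype == bool and len(pred) == 100
    params = est.get_params()
    assert params["theta"] == -1.0 and params["folds"] == 5
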