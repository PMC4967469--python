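"""Logic-model inference for drug response (LOBICO-style).

Finds the optimal two-level boolean formula over binary CFE features that
explains binarized drug sensitivity. Cell lines are labeled sensitive
(IC50 <= threshold theta) or resistant, and weighted by their continuous
distance |ln IC50 - theta| so confidently sensitive/resistant lines count
more; weights are normalized to 0.5 per class so the objective is
balanced. The optimizer enumerates all formulas of a given complexity
(K clauses of M literals, DNF = OR of ANDs or CNF = AND of ORs, literals
possibly negated) and returns the one minimizing total misclassified
weight subject to a training-specificity constraint (default >= 80%).
Model complexity is selected by stratified 5-fold cross-validation over
eight candidate complexities, and significance is assessed by permuting
the IC50 vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement, product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

#: the eight candidate complexities (K clauses, M literals per clause)
DEFAULT_COMPLEXITIES: Tuple[Tuple[int, int], ...] = (
    (1, 1), (1, 2), (2, 1), (1, 3), (3, 1), (1, 4), (4, 1), (2, 2),
)

MAX_FEATURES_PER_MODEL = 4


@dataclass(frozen=True)
class LogicFormula:
    """Two-level boolean formula over (cfe_id, negated) literals."""

    clauses: Tuple[Tuple[Tuple[str, bool], ...], ...]
    form: str = "dnf"  # dnf: OR of ANDs; cnf: AND of ORs

    def __post_init__(self):
        if self.form not in ("dnf", "cnf"):
            raise ValueError(f"form must be dnf or cnf, got {self.form!r}")

    @property
    def features(self) -> Tuple[str, ...]:
        return tuple(sorted({f for cl in self.clauses for f, _ in cl}))

    def __str__(self):
        inner, outer = (" & ", " | ") if self.form == "dnf" else (" | ", " & ")
        parts = []
        for cl in self.clauses:
            lits = inner.join(("~" if neg else "") + f for f, neg in cl)
            parts.append(f"({lits})" if len(cl) > 1 and len(self.clauses) > 1 else lits)
        return outer.join(parts)


@dataclass
class LogicModel:
    """A fitted logic model: formula + threshold + training metrics."""

    formula: Optional[LogicFormula]     # None = null model (all resistant)
    threshold: float                    # ln-IC50 binarization cutoff theta
    train_error: float                  # weighted misclassification, [0, 1]
    precision: Optional[float] = None
    recall: Optional[float] = None
    specificity: Optional[float] = None
    feasible: bool = True

    @property
    def features(self) -> Tuple[str, ...]:
        return self.formula.features if self.formula is not None else ()


def evaluate_formula(formula: LogicFormula, features: pd.DataFrame) -> np.ndarray:
    """Predicted sensitivity of each sample under a formula.

    Returns a float array: 1.0 predicted sensitive, 0.0 resistant, NaN for
    samples with a missing value in any feature the formula uses (those
    samples are thereby excluded from downstream metrics).
    """
    used = formula.features
    absent = [f for f in used if f not in features.columns]
    if absent:
        raise KeyError(f"formula references unknown features: {absent}")
    X = features[list(used)].to_numpy(dtype=float)
    excluded = np.isnan(X).any(axis=1)
    col = {f: i for i, f in enumerate(used)}
    clause_vals = []
    for cl in formula.clauses:
        lits = np.stack(
            [(X[:, col[f]] == 0.0) if neg else (X[:, col[f]] == 1.0)
             for f, neg in cl], axis=1
        )
        clause_vals.append(lits.all(1) if formula.form == "dnf" else lits.any(1))
    C = np.stack(clause_vals, axis=1)
    pred = C.any(1) if formula.form == "dnf" else C.all(1)
    out = pred.astype(float)
    out[excluded] = np.nan
    return out


def binarize_and_weight(ic50s, theta: float) -> Tuple[np.ndarray, np.ndarray]:
    """Label cell lines sensitive/resistant and weight by |IC50 - theta|.

    Sensitive iff ln IC50 <= theta. Weights are proportional to the
    distance from the threshold and normalized so that each class sums to
    0.5; a line exactly at theta gets weight 0 (and the sensitive label).
    """
    x = np.asarray(ic50s, dtype=float)
    labels = x <= theta
    if labels.all() or (~labels).all():
        raise ValueError("both sensitive and resistant classes must be non-empty")
    dist = np.abs(x - theta)
    weights = np.zeros_like(dist)
    for cls in (labels, ~labels):
        tot = dist[cls].sum()
        if tot > 0:
            weights[cls] = 0.5 * dist[cls] / tot
        else:  # all members exactly at theta: spread the class mass evenly
            weights[cls] = 0.5 / cls.sum()
    return labels, weights


def classification_metrics(pred: np.ndarray, labels: np.ndarray):
    """(precision, recall, specificity) with sensitive as positive class.

    Ratios with a zero denominator are returned as None.
    """
    pred = np.asarray(pred, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    specificity = tn / (tn + fp) if tn + fp else None
    return precision, recall, specificity


def model_metrics(model: LogicModel, features: pd.DataFrame, labels):
    """Precision / recall / specificity of a logic model on labeled data."""
    labels = np.asarray(labels, dtype=bool)
    if model.formula is None:
        pred = np.zeros(len(labels), dtype=bool)
        return classification_metrics(pred, labels)
    raw = evaluate_formula(model.formula, features)
    keep = ~np.isnan(raw)
    return classification_metrics(raw[keep] == 1.0, labels[keep])


# ---------------------------------------------------------------------------
# exhaustive enumeration


class _ClauseSpace:
    """All clauses of m literals over distinct features with negations.

    Clause index layout is negation-pattern-major: clause i corresponds to
    feature combination i % C under negation pattern i // C, which keeps
    enumeration order (and hence tie-breaking) deterministic while letting
    coverage be built with vectorized boolean reductions.
    """

    def __init__(self, lits: np.ndarray, feature_ids: Sequence[str], m: int,
                 form: str):
        n, two_f = lits.shape
        F = two_f // 2
        lits_t = lits.T  # (2F, n)
        self.feature_ids = list(feature_ids)
        self.m = m
        self.form = form
        self.feat_combos = np.array(list(combinations(range(F), m)),
                                    dtype=np.int64).reshape(-1, m)
        self.patterns = list(product((False, True), repeat=m))
        blocks = []
        for negs in self.patterns:
            idx = 2 * self.feat_combos + np.array(negs, dtype=np.int64)
            block = lits_t[idx[:, 0]]
            for j in range(1, m):
                nxt = lits_t[idx[:, j]]
                block = (block & nxt) if form == "dnf" else (block | nxt)
            blocks.append(block)
        self.cov = np.vstack(blocks)  # (n_patterns * C, n)

    def spec(self, clause_idx: int) -> Tuple[Tuple[str, bool], ...]:
        C = self.feat_combos.shape[0]
        negs = self.patterns[clause_idx // C]
        feats = self.feat_combos[clause_idx % C]
        return tuple((self.feature_ids[f], neg) for f, neg in zip(feats, negs))

    def features(self, clause_idx: int) -> Tuple[int, ...]:
        C = self.feat_combos.shape[0]
        return tuple(self.feat_combos[clause_idx % C])


def _formula_combos(n_clauses: int, k: int) -> np.ndarray:
    """All K-multisets of clause indices (clause reuse keeps models nested)."""
    if k == 1:
        return np.arange(n_clauses, dtype=np.int64).reshape(-1, 1)
    if k == 2:
        i, j = np.triu_indices(n_clauses)
        return np.column_stack([i, j]).astype(np.int64)
    return np.fromiter(
        (i for combo in combinations_with_replacement(range(n_clauses), k)
         for i in combo),
        dtype=np.int64,
    ).reshape(-1, k)


def _prefilter_features(X: np.ndarray, labels: np.ndarray, weights: np.ndarray,
                        feature_ids: Sequence[str], top: int) -> List[int]:
    """Rank features by their best single-literal weighted accuracy."""
    scores = []
    for j, fid in enumerate(feature_ids):
        col = X[:, j] == 1.0
        for pred in (col, ~col):
            err = weights[pred != labels].sum()
            scores.append((err, fid, j))
    scores.sort()
    kept, seen = [], set()
    for _, fid, j in scores:
        if j not in seen:
            seen.add(j)
            kept.append(j)
        if len(kept) == top:
            break
    return sorted(kept)


def fit_logic_model(
    features: pd.DataFrame,
    labels,
    weights,
    complexity: Tuple[int, int],
    form: str = "dnf",
    min_specificity: float = 0.8,
    prefilter: Optional[int] = 25,
    theta: float = np.nan,
    min_sensitive: int = 5,
    _chunk: int = 20_000,
) -> LogicModel:
    """Exact best formula of the given (K, M) complexity.

    Enumerates every K-clause, M-literal formula (clause reuse allowed, so
    complexities are nested) over the top ``prefilter`` features and
    returns the one minimizing total misclassified weight subject to
    training specificity >= ``min_specificity``. Ties are broken toward
    fewer distinct features, then lexicographic feature ids, then the
    canonical formula string. Infeasibility yields a flagged null model
    predicting all-resistant.
    """
    return _fit_all_complexities(
        features, labels, weights, [complexity], form=form,
        min_specificity=min_specificity, prefilter=prefilter, theta=theta,
        min_sensitive=min_sensitive, _chunk=_chunk,
    )[complexity]


def _fit_all_complexities(
    features: pd.DataFrame,
    labels,
    weights,
    complexities: Sequence[Tuple[int, int]],
    form: str = "dnf",
    min_specificity: float = 0.8,
    prefilter: Optional[int] = 25,
    theta: float = np.nan,
    min_sensitive: int = 5,
    _chunk: int = 20_000,
) -> Dict[Tuple[int, int], LogicModel]:
    """Fit every requested complexity, sharing literal/clause caches."""
    labels = np.asarray(labels, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    if labels.sum() < min_sensitive:
        raise ValueError(
            f"need >= {min_sensitive} sensitive samples, got {int(labels.sum())}"
        )
    X = features.to_numpy(dtype=float)
    feature_ids = list(features.columns)
    if prefilter is not None and len(feature_ids) > prefilter:
        keep = _prefilter_features(X, labels, weights, feature_ids, prefilter)
        X = X[:, keep]
        feature_ids = [feature_ids[j] for j in keep]

    n, F = X.shape
    lits = np.empty((n, 2 * F), dtype=bool)
    lits[:, 0::2] = X == 1.0
    lits[:, 1::2] = X == 0.0

    neg_mask = (~labels).astype(np.float64)
    n_neg = int((~labels).sum())
    # err = w_pos_total + cov @ signed: a covered resistant line adds its
    # weight (false positive), a covered sensitive line removes its miss.
    signed = np.where(labels, -weights, weights)
    w_pos_total = float(weights[labels].sum())

    spaces: Dict[int, _ClauseSpace] = {}
    out: Dict[Tuple[int, int], LogicModel] = {}
    for K, M in complexities:
        if M not in spaces:
            spaces[M] = _ClauseSpace(lits, feature_ids, M, form)
        space = spaces[M]
        cov = space.cov
        combos = _formula_combos(cov.shape[0], K)

        best_err = np.inf
        best_candidates: List[Tuple] = []
        for start in range(0, combos.shape[0], _chunk):
            chunk = combos[start:start + _chunk]
            agg = cov[chunk[:, 0]].copy()
            for j in range(1, K):
                if form == "dnf":
                    agg |= cov[chunk[:, j]]
                else:
                    agg &= cov[chunk[:, j]]
            aggf = agg.astype(np.float64)
            err = w_pos_total + aggf @ signed
            if n_neg:
                fp = aggf @ neg_mask
                err[(n_neg - fp) / n_neg < min_specificity] = np.inf
            chunk_min = err.min() if err.size else np.inf
            if chunk_min < best_err - 1e-12:
                best_err = chunk_min
                best_candidates = []
            if np.isfinite(best_err):
                for t in np.flatnonzero(err <= best_err + 1e-12):
                    best_candidates.append(tuple(chunk[t]))

        if not np.isfinite(best_err):
            null = LogicModel(None, theta, w_pos_total, feasible=False)
            null.precision, null.recall, null.specificity = (
                classification_metrics(np.zeros(n, dtype=bool), labels))
            out[(K, M)] = null
            continue

        def tiekey(combo):
            clause_specs = tuple(sorted(space.spec(i) for i in combo))
            feats = tuple(sorted({f for cl in clause_specs for f, _ in cl}))
            return (len(feats), feats, clause_specs)

        chosen = min(best_candidates, key=tiekey)
        formula = LogicFormula(
            tuple(sorted(space.spec(i) for i in chosen)), form=form)
        pred = evaluate_formula(
            formula, pd.DataFrame(X, columns=feature_ids)) == 1.0
        prec, rec, spec_ = classification_metrics(pred, labels)
        out[(K, M)] = LogicModel(
            formula, theta, float(weights[pred != labels].sum()),
            precision=prec, recall=rec, specificity=spec_,
        )
    return out


# ---------------------------------------------------------------------------
# model selection


@dataclass
class LobicoResult:
    """Outcome of CV complexity selection (and optional permutation test)."""

    cv_errors: pd.Series                  # mean held-out error per complexity
    selected_complexity: Tuple[int, int]
    model: LogicModel                     # refit on all data
    fold_models: Dict[Tuple[int, int], List[LogicModel]] = field(default_factory=dict)
    permutation_p: Optional[float] = None
    fdr: Optional[float] = None

    @property
    def cv_error(self) -> float:
        return float(self.cv_errors[str(self.selected_complexity)])

    @property
    def predictive(self) -> Optional[bool]:
        if self.permutation_p is None:
            return None
        if self.fdr is None:
            return self.permutation_p < 0.05
        return self.permutation_p < 0.05 and self.fdr < 0.05


def _holdout_error(model: LogicModel, features: pd.DataFrame,
                   ic50s: np.ndarray, theta: float) -> float:
    x = np.asarray(ic50s, dtype=float)
    labels = x <= theta
    if labels.all() or (~labels).all():
        # degenerate fold: weight the single present class to 0.5
        dist = np.abs(x - theta)
        tot = dist.sum()
        weights = 0.5 * dist / tot if tot > 0 else np.full(x.size, 0.5 / x.size)
    else:
        labels, weights = binarize_and_weight(x, theta)
    if model.formula is None:
        pred = np.zeros(len(labels), dtype=bool)
    else:
        pred = evaluate_formula(model.formula, features) == 1.0
    return float(weights[pred != labels].sum())


def cross_validate(
    features: pd.DataFrame,
    ic50s,
    theta: float,
    complexities: Iterable[Tuple[int, int]] = DEFAULT_COMPLEXITIES,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    min_specificity: float = 0.8,
    prefilter: Optional[int] = 25,
    form: str = "dnf",
) -> LobicoResult:
    """Select model complexity by repeated stratified K-fold CV.

    The CV error of a complexity is the weighted misclassification on
    held-out folds (weights re-derived within each held-out fold),
    averaged over folds and repeats. The complexity with minimal mean CV
    error wins (ties toward the earlier, simpler entry of the candidate
    list) and is refit on all data.
    """
    ic50s = np.asarray(ic50s, dtype=float)
    labels, _ = binarize_and_weight(ic50s, theta)
    if labels.sum() < 5:
        raise ValueError("need >= 5 sensitive cell lines")
    complexities = list(complexities)
    errors = {c: [] for c in complexities}
    fold_models: Dict[Tuple[int, int], List[LogicModel]] = {c: [] for c in complexities}
    y = labels.astype(int)
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(seed + rep) % (2**31))
        for train_idx, test_idx in skf.split(features, y):
            tr_labels, tr_weights = binarize_and_weight(ic50s[train_idx], theta)
            if tr_labels.sum() < 1:
                continue
            Xtr = features.iloc[train_idx]
            Xte = features.iloc[test_idx]
            fits = _fit_all_complexities(
                Xtr, tr_labels, tr_weights, complexities, form=form,
                min_specificity=min_specificity, prefilter=prefilter,
                theta=theta, min_sensitive=1)
            for c in complexities:
                m = fits[c]
                errors[c].append(_holdout_error(m, Xte, ic50s[test_idx], theta))
                fold_models[c].append(m)
    mean_err = pd.Series({str(c): float(np.mean(errors[c])) for c in complexities})
    selected = complexities[int(np.argmin([mean_err[str(c)] for c in complexities]))]
    full_labels, full_weights = binarize_and_weight(ic50s, theta)
    final = fit_logic_model(features, full_labels, full_weights, selected,
                            form=form, min_specificity=min_specificity,
                            prefilter=prefilter, theta=theta)
    return LobicoResult(mean_err, selected, final, fold_models=fold_models)


def permutation_significance(
    observed: LobicoResult,
    features: pd.DataFrame,
    ic50s,
    theta: float,
    n_perm: int = 100,
    seed: int = 0,
    **cv_kwargs,
) -> float:
    """Permutation p-value for the selected model's CV error.

    IC50s are permuted across samples and the full CV selection is rerun;
    p = (1 + #{permuted CV error <= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    ic50s = np.asarray(ic50s, dtype=float)
    rng = np.random.default_rng(seed)
    obs = observed.cv_error
    hits = 0
    for i in range(n_perm):
        perm = rng.permutation(ic50s)
        res = cross_validate(features, perm, theta,
                             seed=int(rng.integers(2**31)), **cv_kwargs)
        if res.cv_error <= obs:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def feature_importance(results: Dict[str, LobicoResult],
                       classes: Optional[Dict[str, str]] = None):
    """Normalized feature-importance scores across drugs.

    A feature's raw score is its frequency of inclusion in the models fit
    across CV folds x repeats at each drug's selected complexity (plus the
    final refit model). Scores are normalized to sum to 1 over features;
    with a cfe_id -> class map they are also aggregated per CFE class.
    """
    counts: Dict[str, float] = {}
    for res in results.values():
        models = list(res.fold_models.get(res.selected_complexity, [])) + [res.model]
        for m in models:
            for f in m.features:
                counts[f] = counts.get(f, 0.0) + 1.0 / len(models)
    total = sum(counts.values())
    per_feature = pd.Series(
        {f: v / total for f, v in counts.items()} if total else {}, dtype=float
    ).sort_values(ascending=False)
    per_class = None
    if classes is not None:
        per_class = per_feature.groupby(
            per_feature.index.map(lambda f: classes.get(f, "other"))
        ).sum()
    return per_feature, per_class


class LogicModelCV(BaseEstimator):
    """Sklearn-style estimator for LOBICO logic-model inference.

    fit(X, y) takes a binary feature DataFrame and continuous ln-IC50
    vector, selects the best of the eight candidate complexities by
    stratified CV, refits on all data and (optionally) computes a
    permutation p-value. predict(X) returns boolean sensitivity calls.

    Parameters
    ----------
    theta : float or "max-conc"-derived cutoff supplied by the caller;
        the ln-IC50 binarization threshold.
    """

    def __init__(self, theta: float = 0.0,
                 complexities: Sequence[Tuple[int, int]] = DEFAULT_COMPLEXITIES,
                 folds: int = 5, repeats: int = 5, min_specificity: float = 0.8,
                 prefilter: Optional[int] = 25, form: str = "dnf",
                 n_perm: int = 0, random_state: int = 0):
        self.theta = theta
        self.complexities = complexities
        self.folds = folds
        self.repeats = repeats
        self.min_specificity = min_specificity
        self.prefilter = prefilter
        self.form = form
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        cv_kwargs = dict(
            complexities=list(self.complexities), folds=self.folds,
            repeats=self.repeats, min_specificity=self.min_specificity,
            prefilter=self.prefilter, form=self.form,
        )
        result = cross_validate(X, y, self.theta, seed=self.random_state,
                                **cv_kwargs)
        if self.n_perm:
            result.permutation_p = permutation_significance(
                result, X, y, self.theta, n_perm=self.n_perm,
                seed=self.random_state, **cv_kwargs)
        self.result_ = result
        self.model_ = result.model
        self.complexity_ = result.selected_complexity
        self.cv_errors_ = result.cv_errors
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("LogicModelCV is not fitted")
        if self.model_.formula is None:
            return np.zeros(len(X), dtype=bool)
        return evaluate_formula(self.model_.formula, X) == 1.0
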