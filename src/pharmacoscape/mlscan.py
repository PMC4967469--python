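"""Drug-response prediction from combinations of molecular data types.

Per drug, out-of-fold predictive performance (Pearson r of observed vs
predicted ln-IC50) is measured for every non-empty combination of feature
views (driver mutations, copy-number segments, methylation calls, gene
expression, tissue one-hot) using penalized linear models (elastic net)
or tree ensembles (random forest). A model counts as predictive when its
r clears a threshold; thresholds can be the framework's fixed defaults
(0.21 pan-cancer, 0.25 cancer-specific) or re-derived from the empirical
distribution of r values by fitting a two-component Gaussian mixture and
requiring a 9:1 posterior odds of belonging to the informative component.
The best predictive combination per drug is its "lead model".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import KFold

PAN_CANCER_R_THRESHOLD = 0.21
CANCER_SPECIFIC_R_THRESHOLD = 0.25
MIN_SAMPLES = 40
POSTERIOR_ODDS = 9.0


@dataclass
class PredictorPerformance:
    drug_id: str
    combination: Tuple[str, ...]
    method: str
    r_obs_pred: float
    n: int
    predictive: Optional[bool] = None
    lead: bool = False


def build_feature_views(views: Dict[str, pd.DataFrame],
                        combination: Iterable[str],
                        samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Column-wise concatenation of the selected feature views.

    Binary views pass through unchanged; a view tagged ``expression`` is
    standardized per feature (mean 0, sd 1). Views must share sample ids.
    """
    combination = list(combination)
    if not combination:
        raise ValueError("empty view combination")
    unknown = [v for v in combination if v not in views]
    if unknown:
        raise KeyError(f"unknown views: {unknown}")
    if samples is None:
        samples = views[combination[0]].index
        for tag in combination[1:]:
            samples = samples.intersection(views[tag].index)
    blocks = []
    for tag in combination:
        block = views[tag].loc[samples].astype(float)
        if tag == "expression":
            sd = block.std(ddof=0).replace(0.0, 1.0)
            block = (block - block.mean()) / sd
        blocks.append(block.add_prefix(f"{tag}:"))
    return pd.concat(blocks, axis=1)


def tissue_view(annotations: pd.DataFrame) -> pd.DataFrame:
    """One-hot cancer-type indicator view."""
    return pd.get_dummies(annotations["cancer_type"]).astype(float)


def _pearson(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def _oof_pearson(y: np.ndarray, pred: np.ndarray, fold_ids: np.ndarray) -> float:
    """Pooled observed-vs-predicted Pearson r with within-fold centering.

    Held-out predictions hover around each training fold's mean, which is
    anti-correlated with the held-out fold's mean; pooling raw values
    therefore biases r negative under a null response. Centering observed
    and predicted values within each outer fold removes that artifact and
    leaves genuine signal untouched.
    """
    yc, pc = y.astype(float).copy(), pred.astype(float).copy()
    for f in np.unique(fold_ids):
        m = fold_ids == f
        yc[m] -= yc[m].mean()
        pc[m] -= pc[m].mean()
    return _pearson(yc, pc)


def fit_predictor(X: pd.DataFrame, y: pd.Series, method: str = "penalized_linear",
                  folds: int = 5, seed: int = 0,
                  drug_id: str = "", combination: Tuple[str, ...] = ()
                  ) -> PredictorPerformance:
    """Out-of-fold performance of one model on one drug.

    Outer K-fold cross-validation collects held-out predictions;
    hyperparameters (elastic-net alpha path) are tuned on inner folds of
    each training split. r_obs_pred is the Pearson correlation of observed
    and out-of-fold predicted ln-IC50.
    """
    keep = y.notna() & X.notna().all(axis=1)
    Xc, yc = X.loc[keep].to_numpy(), y.loc[keep].to_numpy()
    if len(yc) < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} complete cases, got {len(yc)}")
    if np.std(yc) == 0:
        return PredictorPerformance(drug_id, tuple(combination), method,
                                    np.nan, len(yc))
    oof = np.full(len(yc), np.nan)
    fold_ids = np.zeros(len(yc), dtype=int)
    outer = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(outer.split(Xc)):
        fold_ids[test_idx] = fold
        if method == "penalized_linear":
            model = ElasticNetCV(
                l1_ratio=[0.2, 0.5, 0.9], alphas=30, cv=5,
                random_state=seed, max_iter=5000,
            )
        elif method == "tree_ensemble":
            model = RandomForestRegressor(
                n_estimators=200, min_samples_leaf=3, random_state=seed,
                n_jobs=1,
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xc[train_idx], yc[train_idx])
        oof[test_idx] = model.predict(Xc[test_idx])
    return PredictorPerformance(
        drug_id, tuple(combination), method, _oof_pearson(yc, oof, fold_ids),
        len(yc)
    )


def _powerset(tags: Sequence[str]):
    return chain.from_iterable(
        combinations(tags, k) for k in range(1, len(tags) + 1))


def scan_combinations(drug_id: str, y: pd.Series, views: Dict[str, pd.DataFrame],
                      method: str = "penalized_linear", mode: str = "pan_cancer",
                      folds: int = 5, seed: int = 0
                      ) -> List[PredictorPerformance]:
    """One out-of-fold performance per non-empty view combination.

    Pan-cancer mode admits the tissue view as a candidate; cancer-specific
    mode excludes it. View tags are sorted so results do not depend on
    dict ordering.
    """
    tags = sorted(views)
    if mode != "pan_cancer" and "tissue" in tags:
        tags.remove("tissue")
    results = []
    for combo in _powerset(tags):
        X = build_feature_views(views, combo)
        shared = X.index.intersection(y.dropna().index)
        results.append(
            fit_predictor(X.loc[shared], y.loc[shared], method=method,
                          folds=folds, seed=seed, drug_id=drug_id,
                          combination=combo)
        )
    return results


def derive_predictive_threshold(r_values, posterior_odds: float = POSTERIOR_ODDS,
                                grid_size: int = 2001):
    """Mixture-derived minimum r for calling a model predictive.

    Fits a 2-component Gaussian mixture to all models' observed-vs-
    predicted correlations, takes the higher-mean component as the
    informative one, and returns the smallest r from which the posterior
    odds informative:non-informative stay >= ``posterior_odds`` (first
    sustained crossing on a dense grid). Indistinguishable components
    yield +inf with a warning.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 50:
        raise ValueError(f"need >= 50 r values, got {r.size}")
    rr = r.reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=0, reg_covar=1e-8).fit(rr)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=0,
                         reg_covar=1e-8).fit(rr)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    (m_lo, m_hi) = means[order]
    (s_lo, s_hi) = sds[order]
    (w_lo, w_hi) = gm.weights_[order]
    if gm.bic(rr) >= gm1.bic(rr) or min(w_lo, w_hi) < 1e-3:
        warnings.warn("mixture components indistinguishable; no threshold",
                      stacklevel=2)
        return np.inf
    grid = np.linspace(r.min() - 0.05, r.max() + 0.5, grid_size)
    log_odds = (
        np.log(w_hi) + stats.norm.logpdf(grid, m_hi, s_hi)
        - np.log(w_lo) - stats.norm.logpdf(grid, m_lo, s_lo)
    )
    above = log_odds >= np.log(posterior_odds)
    # first index from which the condition holds for the rest of the grid
    sustained = np.flip(np.logical_and.accumulate(np.flip(above)))
    idx = np.flatnonzero(sustained)
    if idx.size == 0:
        warnings.warn("posterior odds never reach the required ratio",
                      stacklevel=2)
        return np.inf
    i = idx[0]
    if i == 0:
        return float(grid[0])
    # refine the crossing between the bracketing grid points
    from scipy.optimize import brentq
    f = lambda t: (
        np.log(w_hi) + stats.norm.logpdf(t, m_hi, s_hi)
        - np.log(w_lo) - stats.norm.logpdf(t, m_lo, s_lo)
        - np.log(posterior_odds)
    )
    try:
        return float(brentq(f, grid[i - 1], grid[i]))
    except ValueError:
        return float(grid[i])


def select_lead_models(performances: Iterable[PredictorPerformance],
                       threshold_pan: float = PAN_CANCER_R_THRESHOLD,
                       threshold_specific: float = CANCER_SPECIFIC_R_THRESHOLD,
                       mode: str = "pan_cancer"):
    """Flag predictive models and pick each drug's lead model.

    A model is predictive iff its r clears the mode's threshold; the lead
    model is the predictive model with maximal r (ties: fewer data types,
    then lexicographic combination). Returns (lead table DataFrame,
    usage summary Series counting lead models per data-type combination,
    n_drugs_without_predictive_model).
    """
    threshold = threshold_pan if mode == "pan_cancer" else threshold_specific
    by_drug: Dict[str, List[PredictorPerformance]] = {}
    for perf in performances:
        perf.predictive = bool(np.isfinite(perf.r_obs_pred)
                               and perf.r_obs_pred >= threshold)
        perf.lead = False
        by_drug.setdefault(perf.drug_id, []).append(perf)
    rows = []
    n_without = 0
    for drug in sorted(by_drug):
        candidates = [p for p in by_drug[drug] if p.predictive]
        if not candidates:
            n_without += 1
            continue
        lead = min(candidates,
                   key=lambda p: (-p.r_obs_pred, len(p.combination),
                                  p.combination))
        lead.lead = True
        rows.append((drug, "+".join(lead.combination), lead.method,
                     lead.r_obs_pred, lead.n))
    lead_table = pd.DataFrame(
        rows, columns=["drug_id", "combination", "method", "r_obs_pred", "n"])
    usage = (lead_table.groupby("combination").size().sort_values(ascending=False)
             if len(lead_table) else pd.Series(dtype=int))
    return lead_table, usage, n_without
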