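"""Informative CpG island (iCpG) detection and methylation binarization.

Promoter CpG islands whose methylation beta values show a multimodal
distribution across samples carry a binarizable hyper-/non-hypermethylated
signal. Informativeness is decided by comparing 1- vs 2-component Gaussian
mixtures on logit-transformed betas (BIC), requiring the two component
means to be separated and both components to carry non-trivial weight.
The discretization threshold is the beta value between the two component
means where posterior membership is equal.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from .matrix import AlterationMatrix

_LOGIT_EPS = 1e-4
MIN_SAMPLES = 30


class MethylationTable:
    """Island x sample beta values in [0, 1] with a cancer type per sample."""

    def __init__(self, betas: pd.DataFrame, cancer_types: pd.Series):
        betas = betas.astype(float)
        arr = betas.to_numpy()
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
            raise ValueError("beta values must lie in [0, 1]")
        missing = betas.columns.difference(cancer_types.index)
        if len(missing):
            raise ValueError(f"samples without cancer type: {list(missing)[:5]}")
        self.betas = betas
        self.cancer_types = cancer_types.loc[betas.columns]

    @property
    def island_ids(self):
        return list(self.betas.index)

    @property
    def sample_ids(self):
        return list(self.betas.columns)


def _fit_mixture(x: np.ndarray, k: int) -> GaussianMixture:
    return GaussianMixture(
        n_components=k, covariance_type="full", n_init=5, random_state=0,
        reg_covar=1e-6, max_iter=500,
    ).fit(x.reshape(-1, 1))


def detect_informative_cpg(
    betas,
    min_separation: float = 1.0,
    min_component_weight: float = 0.05,
) -> Tuple[bool, Optional[float]]:
    """Decide whether a CpG island's beta distribution is bimodal.

    Parameters
    ----------
    betas : array-like of beta values in [0, 1], n >= 30.
    min_separation : float
        Minimum distance between the two component means, logit scale.
    min_component_weight : float
        Minimum mixing weight of each component.

    Returns
    -------
    (informative, threshold)
        ``threshold`` is the beta value between the two component means
        with equal posterior membership; None when not informative.
    """
    x = np.asarray(betas, dtype=float)
    if x.ndim != 1:
        raise ValueError("betas must be a 1-d vector")
    if np.any(~np.isfinite(x)) or x.min() < 0 or x.max() > 1:
        raise ValueError("beta values must be finite and in [0, 1]")
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} beta values, got {x.size}")

    z = logit(np.clip(x, _LOGIT_EPS, 1 - _LOGIT_EPS))
    if np.var(z) < 1e-12:  # constant vector: degenerate, not informative
        return False, None

    gm1 = _fit_mixture(z, 1)
    gm2 = _fit_mixture(z, 2)
    if gm2.bic(z.reshape(-1, 1)) >= gm1.bic(z.reshape(-1, 1)):
        return False, None
    means = gm2.means_.ravel()
    order = np.argsort(means)
    m_lo, m_hi = means[order]
    w_lo, w_hi = gm2.weights_[order]
    s_lo, s_hi = np.sqrt(gm2.covariances_.ravel()[order])
    if (m_hi - m_lo) < min_separation:
        return False, None
    if min(w_lo, w_hi) < min_component_weight:
        return False, None

    def log_ratio(t):
        # log posterior(hi) - log posterior(lo) at point t
        return (
            np.log(w_hi) - 0.5 * np.log(2 * np.pi * s_hi**2)
            - (t - m_hi) ** 2 / (2 * s_hi**2)
        ) - (
            np.log(w_lo) - 0.5 * np.log(2 * np.pi * s_lo**2)
            - (t - m_lo) ** 2 / (2 * s_lo**2)
        )

    try:
        t_star = brentq(log_ratio, m_lo, m_hi)
    except ValueError:
        # no sign change between the means (extreme weight imbalance)
        return False, None
    return True, float(expit(t_star))


def binarize_methylation(table: MethylationTable, thresholds: Dict[str, float],
                         cohort: str = "cell_line") -> AlterationMatrix:
    """Binarize beta values: hypermethylated (1) iff beta > threshold.

    Islands without a threshold (non-informative) are dropped. The strict
    inequality makes the boundary deterministic: beta exactly at the
    threshold is called non-hypermethylated.
    """
    kept = [i for i in table.island_ids if i in thresholds]
    values = {}
    for island in kept:
        thr = thresholds[island]
        row = table.betas.loc[island]
        values[island] = np.where(row.isna(), np.nan, (row > thr).astype(float))
    df = pd.DataFrame(values, index=table.sample_ids)
    ann = pd.DataFrame(
        {
            "cohort": cohort,
            "cancer_type": table.cancer_types,
            "msi": "unknown",
        },
        index=table.sample_ids,
    )
    return AlterationMatrix(df, ann)


class CpGMixtureBinarizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: detect iCpGs, then binarize.

    ``fit`` runs :func:`detect_informative_cpg` per island of a
    :class:`MethylationTable`; ``transform`` returns the binarized
    :class:`AlterationMatrix` restricted to informative islands.

    Attributes
    ----------
    thresholds_ : dict island id -> beta threshold (informative islands only)
    informative_ : pandas.Series of bool per island
    """

    def __init__(self, min_separation: float = 1.0,
                 min_component_weight: float = 0.05):
        self.min_separation = min_separation
        self.min_component_weight = min_component_weight

    def fit(self, table: MethylationTable, y=None):
        self.thresholds_ = {}
        flags = {}
        for island in table.island_ids:
            betas = table.betas.loc[island].dropna().to_numpy()
            informative, thr = detect_informative_cpg(
                betas, self.min_separation, self.min_component_weight
            )
            flags[island] = informative
            if informative:
                self.thresholds_[island] = thr
        self.informative_ = pd.Series(flags)
        return self

    def transform(self, table: MethylationTable) -> AlterationMatrix:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("CpGMixtureBinarizer is not fitted")
        return binarize_methylation(table, self.thresholds_)
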