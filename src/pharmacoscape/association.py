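"""Drug-CFE ANOVA association scan with effect-size gating.

For every testable (drug, CFE) pair, drug response (ln IC50) is regressed
on covariates (cancer type and MSI status in the pan-cancer scan; MSI
only within one cancer type) plus the binary CFE status, and the CFE term
is tested by an added-last F-test. Effect sizes are Cohen's D (pooled-sd
standardized mean difference) and the two Glass deltas (mean difference
over each group's own sd). Significance gates follow the framework's
conventions: p < 1e-3 and Benjamini-Hochberg FDR < 25%, with the
"large effect" label additionally requiring Glass delta > 1 in both the
altered and unaltered populations. Negative mean differences (lower IC50
in carriers) are sensitizing; positive are resistance associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .doseresponse import DrugResponseTable
from .matrix import AlterationMatrix

P_THRESHOLD = 1e-3
FDR_THRESHOLD = 0.25
GLASS_THRESHOLD = 1.0
MIN_GROUP = 3
MIN_CANCER_TYPE_LINES = 16  # cancer-specific scans need > 15 cell lines


def effect_sizes(pos, neg) -> Tuple[float, float, float]:
    """(cohens_d, glass_pos, glass_neg) for two response groups.

    cohens_d is signed (positive - negative means over the pooled sd);
    the Glass deltas are the absolute mean difference standardized by each
    group's own sd. Sample sds use the n-1 denominator. A zero-variance
    group leaves its Glass delta (and, if pooled, Cohen's D) as NaN.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 samples per group")
    diff = pos.mean() - neg.mean()
    s_pos, s_neg = pos.std(ddof=1), neg.std(ddof=1)
    s_pooled = np.sqrt(
        ((pos.size - 1) * s_pos**2 + (neg.size - 1) * s_neg**2)
        / (pos.size + neg.size - 2)
    )
    cohens_d = diff / s_pooled if s_pooled > 0 else np.nan
    glass_pos = abs(diff) / s_pos if s_pos > 0 else np.nan
    glass_neg = abs(diff) / s_neg if s_neg > 0 else np.nan
    return float(cohens_d), float(glass_pos), float(glass_neg)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN p-values pass through)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _design(covariates: Optional[pd.DataFrame]) -> np.ndarray:
    """Intercept + one-hot (drop-first) encoding of categorical covariates."""
    n = len(covariates) if covariates is not None else 0
    cols = [np.ones((n, 1))]
    if covariates is not None:
        for name in covariates.columns:
            dummies = pd.get_dummies(covariates[name].astype(str), drop_first=True)
            if dummies.shape[1]:
                cols.append(dummies.to_numpy(dtype=float))
    return np.hstack(cols)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> Tuple[float, int]:
    """(residual sum of squares, rank) of an OLS fit."""
    beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rss.size == 0:  # rank-deficient or saturated: compute residuals directly
        resid = y - X @ beta
        return float(resid @ resid), int(rank)
    return float(rss[0]), int(rank)


def fit_association(response, cfe, covariates: Optional[pd.DataFrame] = None
                    ) -> float:
    """Added-last F-test p-value for a CFE term in a linear model.

    Fits response ~ covariates and response ~ covariates + cfe by OLS and
    tests the CFE term with the nested-model F statistic. With no
    covariates this reduces to the pooled-variance two-sample t-test
    (F = t^2). Returns NaN when the CFE is collinear with the covariates
    (e.g., perfectly confounded with tissue).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(cfe, dtype=float)
    X0 = _design(covariates) if covariates is not None else np.ones((y.size, 1))
    rss0, rank0 = _ols_rss(X0, y)
    X1 = np.hstack([X0, x.reshape(-1, 1)])
    rss1, rank1 = _ols_rss(X1, y)
    if rank1 <= rank0:  # CFE collinear with covariates
        return np.nan
    df_resid = y.size - rank1
    if df_resid <= 0 or rss1 <= 0:
        return np.nan
    F = (rss0 - rss1) / (rss1 / df_resid)
    return float(stats.f.sf(F, 1, df_resid))


@dataclass
class ScanConfig:
    p_threshold: float = P_THRESHOLD
    fdr_threshold: float = FDR_THRESHOLD
    glass_threshold: float = GLASS_THRESHOLD
    min_group: int = MIN_GROUP


@dataclass
class AssociationTable:
    """All tests of one scan, with BH FDR computed over exactly these tests."""

    results: pd.DataFrame
    analysis: str                     # "pan_cancer" or the cancer-type label
    config: ScanConfig = field(default_factory=ScanConfig)
    skipped: List[Tuple[str, str, str]] = field(default_factory=list)

    def significant(self) -> pd.DataFrame:
        return self.results[self.results["significant"]]

    def large_effect(self) -> pd.DataFrame:
        return self.results[self.results["large_effect"]]


_RESULT_COLUMNS = [
    "drug_id", "cfe_id", "analysis", "n_pos", "n_neg", "delta_mean",
    "cohens_d", "glass_pos", "glass_neg", "p_value", "fdr", "significant",
    "large_effect", "direction",
]


def run_scan(responses: DrugResponseTable, alterations: AlterationMatrix,
             mode: str = "pan_cancer", cancer_type: Optional[str] = None,
             config: Optional[ScanConfig] = None) -> AssociationTable:
    """ANOVA scan of all testable (drug, CFE) pairs.

    Pan-cancer mode uses cancer type + MSI as covariates over all cell
    lines; cancer-specific mode restricts to one cancer type (> 15 cell
    lines required) with MSI as the only covariate. BH FDR is computed
    across all tests of the scan; significant iff p < 1e-3 and FDR < 25%,
    large_effect additionally requires both Glass deltas > 1.
    """
    config = config or ScanConfig()
    shared = alterations.values.index.intersection(responses.ln_ic50.index)
    matrix = alterations.subset_samples(shared)
    ann = matrix.annotations
    if mode == "pan_cancer":
        covar_cols = ["cancer_type", "msi"]
        analysis = "pan_cancer"
    elif mode == "cancer_specific":
        if cancer_type is None:
            raise ValueError("cancer_specific mode requires cancer_type")
        keep = ann.index[ann["cancer_type"] == cancer_type]
        if len(keep) < MIN_CANCER_TYPE_LINES:
            raise ValueError(
                f"cancer-specific scan needs > 15 cell lines, "
                f"{cancer_type} has {len(keep)}"
            )
        matrix = matrix.subset_samples(keep)
        ann = matrix.annotations
        covar_cols = ["msi"]
        analysis = cancer_type
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # stable sample order so results are independent of input row order
    order = matrix.values.index.sort_values()
    X = matrix.values.loc[order]
    ann = ann.loc[order]

    rows, skipped = [], []
    cfe_order = sorted(X.columns)
    Xv = X[cfe_order].to_numpy(dtype=float)
    for drug in sorted(responses.drug_ids):
        y_all = responses.ln_ic50[drug].reindex(order).to_numpy(dtype=float)
        keep_y = np.isfinite(y_all)
        yk = y_all[keep_y]
        Xk = Xv[keep_y]
        col_nan = np.isnan(Xk).any(axis=0)
        ann_k = ann.loc[keep_y, covar_cols]

        # fast path: CFE columns complete on this drug's screened lines
        # share the covariate design, so residualize once and batch the
        # added-last F-tests
        fast = np.flatnonzero(~col_nan)
        if fast.size and len(yk):
            D = _design(ann_k)
            M = np.column_stack([yk, Xk[:, fast]])
            beta, _, rank0, _ = np.linalg.lstsq(D, M, rcond=None)
            R = M - D @ beta
            ry, RX = R[:, 0], R[:, 1:]
            ryy = float(ry @ ry)
            rxx = (RX**2).sum(axis=0)
            rxy = RX.T @ ry
            nk = len(yk)
            df_resid = nk - rank0 - 1
            xn = Xk[:, fast]
            n_pos = xn.sum(axis=0)
            n_neg = nk - n_pos
            sum_pos = xn.T @ yk
            sumsq_pos = xn.T @ (yk**2)
            sum_all, sumsq_all = yk.sum(), float(yk @ yk)
            for j, ci in enumerate(fast):
                cfe = cfe_order[ci]
                npos, nneg = int(n_pos[j]), int(n_neg[j])
                if npos < config.min_group or nneg < config.min_group:
                    skipped.append((drug, cfe, "group size below minimum"))
                    continue
                mean_pos = sum_pos[j] / npos
                mean_neg = (sum_all - sum_pos[j]) / nneg
                var_pos = max(sumsq_pos[j] - npos * mean_pos**2, 0.0) / (npos - 1)
                var_neg = max(
                    (sumsq_all - sumsq_pos[j]) - nneg * mean_neg**2, 0.0
                ) / (nneg - 1)
                delta_mean = float(mean_pos - mean_neg)
                s_pooled = np.sqrt(((npos - 1) * var_pos + (nneg - 1) * var_neg)
                                   / (npos + nneg - 2))
                d = delta_mean / s_pooled if s_pooled > 0 else np.nan
                g_pos = abs(delta_mean) / np.sqrt(var_pos) if var_pos > 0 else np.nan
                g_neg = abs(delta_mean) / np.sqrt(var_neg) if var_neg > 0 else np.nan
                if rxx[j] <= 1e-10 * nk or df_resid <= 0:
                    skipped.append((drug, cfe, "collinear with covariates"))
                    continue
                rss1 = ryy - rxy[j]**2 / rxx[j]
                if rss1 <= 0:
                    skipped.append((drug, cfe, "saturated fit"))
                    continue
                F = (ryy - rss1) / (rss1 / df_resid)
                p = float(stats.f.sf(F, 1, df_resid))
                rows.append((drug, cfe, analysis, npos, nneg, delta_mean,
                             d, g_pos, g_neg, p, np.nan, False, False,
                             "sensitizing" if delta_mean < 0 else "resistance"))

        # generic path: columns with missing CFE calls get per-test
        # complete-case handling
        for ci in np.flatnonzero(col_nan):
            cfe = cfe_order[ci]
            x_col = Xk[:, ci]
            keep = np.isfinite(x_col)
            y = yk[keep]
            x = x_col[keep]
            n_pos = int((x == 1).sum())
            n_neg = int((x == 0).sum())
            if n_pos < config.min_group or n_neg < config.min_group:
                skipped.append((drug, cfe, "group size below minimum"))
                continue
            d, g_pos, g_neg = effect_sizes(y[x == 1], y[x == 0])
            delta_mean = float(y[x == 1].mean() - y[x == 0].mean())
            p = fit_association(y, x, ann_k.loc[keep])
            if np.isnan(p):
                skipped.append((drug, cfe, "collinear with covariates"))
                continue
            rows.append((drug, cfe, analysis, n_pos, n_neg, delta_mean,
                         d, g_pos, g_neg, p, np.nan, False, False,
                         "sensitizing" if delta_mean < 0 else "resistance"))
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        df["significant"] = (
            (df["p_value"] < config.p_threshold)
            & (df["fdr"] < config.fdr_threshold)
        )
        df["large_effect"] = (
            df["significant"]
            & (df["glass_pos"] > config.glass_threshold)
            & (df["glass_neg"] > config.glass_threshold)
        )
    return AssociationTable(df, analysis, config, skipped)


def downsample_experiment(responses: DrugResponseTable,
                          alterations: AlterationMatrix,
                          sizes: Iterable[int], reps: int = 5, seed: int = 0,
                          mode: str = "pan_cancer",
                          cancer_type: Optional[str] = None,
                          config: Optional[ScanConfig] = None) -> pd.DataFrame:
    """Hit retention under random downsampling of the cell-line cohort.

    Reruns the scan on uniform random subsets of each size and reports,
    per (size, rep), the fraction of full-cohort significant and
    large-effect hits retained, plus the mean Cohen's D shift of retained
    hits relative to the full scan.
    """
    full = run_scan(responses, alterations, mode, cancer_type, config)
    n = len(alterations.sample_ids)
    for s in sizes:
        if s >= n:
            raise ValueError(f"downsample size {s} >= cohort size {n}")
    sig_full = set(map(tuple, full.significant()[["drug_id", "cfe_id"]].values))
    le_full = set(map(tuple, full.large_effect()[["drug_id", "cfe_id"]].values))
    d_full = full.results.set_index(["drug_id", "cfe_id"])["cohens_d"]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(reps):
            sub_ids = list(np.asarray(alterations.sample_ids)[
                rng.choice(n, size=size, replace=False)])
            try:
                sub = run_scan(responses, alterations.subset_samples(sub_ids),
                               mode, cancer_type, config)
            except ValueError:
                rows.append((size, rep, np.nan, np.nan, np.nan))
                continue
            sig = set(map(tuple, sub.significant()[["drug_id", "cfe_id"]].values))
            le = set(map(tuple, sub.large_effect()[["drug_id", "cfe_id"]].values))
            d_sub = sub.results.set_index(["drug_id", "cfe_id"])["cohens_d"]
            retained = sig & sig_full
            shift = (
                float((d_sub.loc[list(retained)] - d_full.loc[list(retained)]).mean())
                if retained else np.nan
            )
            rows.append((
                size, rep,
                len(retained) / len(sig_full) if sig_full else np.nan,
                len(le & le_full) / len(le_full) if le_full else np.nan,
                shift,
            ))
    return pd.DataFrame(
        rows, columns=["size", "rep", "sig_retention", "large_effect_retention",
                       "cohens_d_shift"],
    )


def cross_study_validate(table_a: AssociationTable, table_b: AssociationTable,
                         alpha: float = 0.05):
    """Cross-study consistency of two association scans.

    Over shared (drug, CFE) pairs: Pearson correlation of signed -log10
    p-values (sign from delta_mean); for table_a's significant hits, a hit
    validates iff table_b shows p < alpha with the same direction.
    Returns (pearson_r, validation_rate_sensitizing,
    validation_rate_resistance, fisher_p) where fisher_p tests validated
    status against direction.
    """
    a = table_a.results.set_index(["drug_id", "cfe_id"])
    b = table_b.results.set_index(["drug_id", "cfe_id"])
    shared = a.index.intersection(b.index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared (drug, CFE) pairs, got {len(shared)}")
    a, b = a.loc[shared], b.loc[shared]

    def signed_logp(t):
        return -np.log10(np.clip(t["p_value"], 1e-300, None)) * np.sign(
            t["delta_mean"])

    r = float(stats.pearsonr(signed_logp(a), signed_logp(b))[0])
    sig = a[a["significant"]]
    b_sig = b.loc[sig.index]
    validated = (b_sig["p_value"] < alpha) & (
        b_sig["direction"] == sig["direction"])
    rates = {}
    for direction in ("sensitizing", "resistance"):
        mask = sig["direction"] == direction
        rates[direction] = (
            float(validated[mask].mean()) if mask.sum() else np.nan
        )
    table = np.array([
        [int((validated & (sig["direction"] == "sensitizing")).sum()),
         int((~validated & (sig["direction"] == "sensitizing")).sum())],
        [int((validated & (sig["direction"] == "resistance")).sum()),
         int((~validated & (sig["direction"] == "resistance")).sum())],
    ])
    fet_p = float(stats.fisher_exact(table)[1]) if table.sum() else np.nan
    return r, rates["sensitizing"], rates["resistance"], fet_p
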