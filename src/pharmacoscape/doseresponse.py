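"""Dose-response curve summarization: ln-IC50, AUC, replicate concordance.

Each (drug, cell line) screen yields relative viabilities at a dilution
series of concentrations. Curves are summarized by a two-parameter
logistic with asymptotes fixed at 1 (no effect) and 0 (complete kill):

    viability(c) = 1 / (1 + exp(slope * (ln c - ln_ic50)))

AUC is the mean fitted viability over the tested log-concentration
interval, on [0, 1] with 1 = no effect. A cell line is called sensitive
to a drug when its IC50 is at or below the maximal tested concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares


@dataclass
class DoseResponseCurve:
    drug_id: str
    sample_id: str
    concentrations: np.ndarray  # uM, strictly decreasing
    viabilities: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viabilities = np.asarray(self.viabilities, dtype=float)
        if self.concentrations.size < 5:
            raise ValueError("need >= 5 dose points")
        if self.concentrations.size != self.viabilities.size:
            raise ValueError("concentrations and viabilities differ in length")
        if not np.all(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be strictly decreasing")


@dataclass
class CurveFit:
    ln_ic50: float          # ln(uM)
    slope: float            # > 0
    auc: float              # [0, 1]
    rmse: float
    extrapolated: bool      # ln_ic50 above ln(max tested concentration)


def logistic_viability(ln_conc, ln_ic50, slope):
    return 1.0 / (1.0 + np.exp(np.clip(slope * (ln_conc - ln_ic50), -500, 500)))


def compute_auc(ln_ic50: float, slope: float, concentrations) -> float:
    """Mean fitted viability over the tested log-concentration interval.

    Closed form: the antiderivative of the logistic in x = ln c is
    x - softplus(slope * (x - ln_ic50)) / slope.
    """
    ln_c = np.log(np.asarray(concentrations, dtype=float))
    lo, hi = ln_c.min(), ln_c.max()
    if hi == lo:
        return float(np.clip(logistic_viability(lo, ln_ic50, slope), 0, 1))

    def antideriv(x):
        return x - np.logaddexp(0.0, slope * (x - ln_ic50)) / slope

    auc = (antideriv(hi) - antideriv(lo)) / (hi - lo)
    return float(np.clip(auc, 0.0, 1.0))


_SLOPE_GRID = (0.5, 1.0, 2.0, 4.0)


def fit_curve(curve: DoseResponseCurve) -> CurveFit:
    """Least-squares 2-parameter logistic fit of one dose-response curve.

    Deterministic multi-start: slopes {0.5, 1, 2, 4} crossed with ln-IC50
    starts at the quartiles of the tested ln-concentration range; best
    refined solution by SSE wins. ln_ic50 is unconstrained; when it lands
    above the maximal tested concentration the fit is flagged
    ``extrapolated`` (the drug never reached half-kill in range).
    """
    ln_c = np.log(curve.concentrations)
    y = curve.viabilities
    if np.any(~np.isfinite(y)):
        raise ValueError(
            f"non-finite viabilities for ({curve.drug_id}, {curve.sample_id})"
        )

    def resid(params):
        return logistic_viability(ln_c, params[0], np.exp(params[1])) - y

    lo, hi = ln_c.min(), ln_c.max()
    ic50_starts = np.quantile(ln_c, [0.25, 0.5, 0.75])
    best, best_sse = None, np.inf
    for s0 in _SLOPE_GRID:
        for m0 in ic50_starts:
            try:
                sol = least_squares(resid, x0=[m0, np.log(s0)], method="lm",
                                    max_nfev=2000)
            except Exception:
                continue
            sse = float(np.sum(sol.fun**2))
            if sse < best_sse - 1e-15:
                best, best_sse = sol, sse
    if best is None:
        return CurveFit(np.nan, np.nan, np.nan, np.inf, False)
    ln_ic50 = float(best.x[0])
    slope = float(np.exp(best.x[1]))
    rmse = float(np.sqrt(best_sse / y.size))
    return CurveFit(
        ln_ic50=ln_ic50,
        slope=slope,
        auc=compute_auc(ln_ic50, slope, curve.concentrations),
        rmse=rmse,
        extrapolated=ln_ic50 > hi,
    )


class DrugResponseTable:
    """Per (drug, cell line) ln-IC50 and AUC summaries.

    Parameters
    ----------
    ln_ic50 : DataFrame, samples x drugs, ln(uM); NaN = not screened.
    auc : DataFrame aligned with ln_ic50, in [0, 1].
    max_conc : Series per drug, uM.
    """

    def __init__(self, ln_ic50: pd.DataFrame, auc: Optional[pd.DataFrame],
                 max_conc: pd.Series):
        missing = ln_ic50.columns.difference(max_conc.index)
        if len(missing):
            raise ValueError(f"drugs without max_conc: {list(missing)[:5]}")
        self.ln_ic50 = ln_ic50.astype(float)
        self.auc = auc.astype(float) if auc is not None else None
        self.max_conc = max_conc.astype(float).loc[ln_ic50.columns]

    @property
    def drug_ids(self):
        return list(self.ln_ic50.columns)

    @property
    def sample_ids(self):
        return list(self.ln_ic50.index)

    def sensitive_calls(self, drug_id: str) -> pd.Series:
        """Sensitive iff IC50 <= maximal tested concentration (inclusive)."""
        return self.ln_ic50[drug_id] <= np.log(self.max_conc[drug_id])

    def write_tsv(self, path):
        long = self.ln_ic50.stack().rename("ln_ic50").reset_index()
        long.columns = ["sample_id", "drug_id", "ln_ic50"]
        if self.auc is not None:
            auc_long = self.auc.stack().rename("auc").reset_index()
            auc_long.columns = ["sample_id", "drug_id", "auc"]
            long = long.merge(auc_long, on=["sample_id", "drug_id"], how="left")
        long["max_conc"] = long["drug_id"].map(self.max_conc)
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path):
        long = pd.read_csv(path, sep="\t")
        ln = long.pivot(index="sample_id", columns="drug_id", values="ln_ic50")
        auc = (
            long.pivot(index="sample_id", columns="drug_id", values="auc")
            if "auc" in long.columns else None
        )
        max_conc = long.groupby("drug_id")["max_conc"].first()
        return cls(ln, auc, max_conc)


def fit_curves_table(long_df: pd.DataFrame) -> DrugResponseTable:
    """Summarize a long-format dose-response table into a DrugResponseTable.

    Expects columns drug_id, sample_id, conc_uM, viability.
    """
    records = []
    max_conc = {}
    for (drug, sample), grp in long_df.groupby(["drug_id", "sample_id"], sort=True):
        grp = grp.sort_values("conc_uM", ascending=False)
        curve = DoseResponseCurve(
            drug, sample, grp["conc_uM"].to_numpy(), grp["viability"].to_numpy()
        )
        fit = fit_curve(curve)
        records.append((sample, drug, fit.ln_ic50, fit.auc))
        max_conc[drug] = max(max_conc.get(drug, 0.0), grp["conc_uM"].max())
    df = pd.DataFrame(records, columns=["sample_id", "drug_id", "ln_ic50", "auc"])
    ln = df.pivot(index="sample_id", columns="drug_id", values="ln_ic50")
    auc = df.pivot(index="sample_id", columns="drug_id", values="auc")
    return DrugResponseTable(ln, auc, pd.Series(max_conc))


def replicate_concordance(ic50_a: pd.Series, ic50_b: pd.Series, max_conc: float):
    """Concordance of two replicate IC50 profiles of the same drug.

    Returns Pearson r over shared cell lines, the one-sided Fisher exact
    p (log10) for consistency of sensitive/resistant calls, and the 2x2
    contingency table (rows: replicate A sensitive/resistant, columns:
    replicate B).
    """
    shared = ic50_a.dropna().index.intersection(ic50_b.dropna().index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared cell lines, got {len(shared)}")
    a, b = ic50_a.loc[shared], ic50_b.loc[shared]
    r = float(stats.pearsonr(a, b)[0])
    thr = np.log(max_conc)
    sa, sb = a <= thr, b <= thr
    table = np.array([
        [int((sa & sb).sum()), int((sa & ~sb).sum())],
        [int((~sa & sb).sum()), int((~sa & ~sb).sum())],
    ])
    p = stats.fisher_exact(table, alternative="greater")[1]
    return r, float(np.log10(max(p, 1e-300))), table
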