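"""Seeded generators of paired tumor/cell-line cohorts with planted truth.

The simulator emulates the statistical structure the analysis pipeline
assumes: tumors and cell lines of each cancer type share per-type CFE
frequencies (independent Bernoulli draws), informative CpG islands carry
a bimodal methylation signal, and per-drug ln-IC50 responses are a
baseline plus planted additive CFE effects, planted AND/OR logic-rule
effects and Gaussian noise. Every generator is a pure function of
(config, seed) and records its planted ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .catalog import CFE, CFECatalog
from .doseresponse import DrugResponseTable, compute_auc, logistic_viability
from .logic import LogicFormula, evaluate_formula
from .matrix import AlterationMatrix
from .methylation import MethylationTable


@dataclass
class AdditiveEffect:
    drug_id: str
    cfe_id: str
    beta: float  # ln-IC50 shift in carriers; negative = sensitizing


@dataclass
class LogicEffect:
    drug_id: str
    formula: LogicFormula
    beta: float


@dataclass
class CFESpec:
    cfe_class: str
    #: per-cancer-type frequency, or one frequency for all types
    frequency: Union[float, Dict[str, float]]

    def freq_for(self, cancer_type: str) -> float:
        if isinstance(self.frequency, dict):
            return self.frequency.get(cancer_type, 0.0)
        return float(self.frequency)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    cancer_types maps a type label to (n_tumors, n_cell_lines).
    """

    cancer_types: Dict[str, Tuple[int, int]]
    cfe_spec: Dict[str, CFESpec]
    baseline_ic50: Dict[str, float]                  # drug -> mean ln(uM)
    additive_effects: List[AdditiveEffect] = field(default_factory=list)
    logic_effects: List[LogicEffect] = field(default_factory=list)
    noise_sd: float = 0.8                            # ln-IC50 units
    max_conc: Union[float, Dict[str, float]] = 10.0  # uM
    msi_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for t, (nt, nc) in self.cancer_types.items():
            if nt < 1 or nc < 1:
                raise ValueError(f"counts for {t} must be >= 1")
        for cid, spec in self.cfe_spec.items():
            freqs = (spec.frequency.values()
                     if isinstance(spec.frequency, dict) else [spec.frequency])
            for f in freqs:
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"frequency {f} for {cid} outside [0, 1]")
        known = set(self.cfe_spec)
        for eff in self.additive_effects:
            if eff.cfe_id not in known:
                raise ValueError(f"additive effect references unknown CFE {eff.cfe_id}")
        for eff in self.logic_effects:
            for f in eff.formula.features:
                if f not in known:
                    raise ValueError(f"logic effect references unknown CFE {f}")

    def max_conc_for(self, drug_id: str) -> float:
        if isinstance(self.max_conc, dict):
            return float(self.max_conc[drug_id])
        return float(self.max_conc)


@dataclass
class GroundTruth:
    """Planted signal, keyed for downstream recovery tests."""

    additive_effects: List[AdditiveEffect] = field(default_factory=list)
    logic_effects: List[LogicEffect] = field(default_factory=list)
    frequencies: Optional[pd.DataFrame] = None       # cancer type x CFE
    latent_means: Optional[pd.DataFrame] = None      # sample x drug, noiseless
    informative_islands: Optional[pd.Series] = None  # island -> bool
    island_params: Optional[pd.DataFrame] = None


# ---------------------------------------------------------------------------
# default study conditions (desk scale)

DEFAULT_N_TYPES = 8
DEFAULT_TUMORS_PER_TYPE = 120
DEFAULT_LINES_PER_TYPE = 30
DEFAULT_N_CG = 20
DEFAULT_N_RACS_AMP = 8
DEFAULT_N_RACS_DEL = 8
DEFAULT_N_ICPG = 4
DEFAULT_N_DRUGS = 12


def default_config(seed: int = 0,
                   n_types: int = DEFAULT_N_TYPES,
                   tumors_per_type: int = DEFAULT_TUMORS_PER_TYPE,
                   lines_per_type: int = DEFAULT_LINES_PER_TYPE,
                   n_drugs: int = DEFAULT_N_DRUGS) -> SimulationConfig:
    """Desk-scale default conditions.

    Per-type CFE frequencies are drawn once (from the config seed) from a
    long-tailed Beta(0.8, 4) rescaled into [0.02, 0.9], mimicking the
    skewed frequency spectra of driver alterations in tumor cohorts, and
    are distinct across cancer types so that tissue identity is a
    recoverable signal. A sensitizing additive effect and one (A OR B)
    logic rule are planted on the first two drugs.
    """
    rng = np.random.default_rng(seed)
    types = [f"CT{i + 1:02d}" for i in range(n_types)]
    cancer_types = {t: (tumors_per_type, lines_per_type) for t in types}
    names = (
        [f"GENE{i + 1:02d}_mut" for i in range(DEFAULT_N_CG)]
        + [f"RACS{i + 1:02d}_amp" for i in range(DEFAULT_N_RACS_AMP)]
        + [f"RACS{i + 1:02d}_del" for i in range(DEFAULT_N_RACS_DEL)]
        + [f"CPG{i + 1:02d}_hyp" for i in range(DEFAULT_N_ICPG)]
    )
    classes = (
        ["CG"] * DEFAULT_N_CG
        + ["RACS_amp"] * DEFAULT_N_RACS_AMP
        + ["RACS_del"] * DEFAULT_N_RACS_DEL
        + ["iCpG"] * DEFAULT_N_ICPG
    )
    cfe_spec = {}
    for name, cls in zip(names, classes):
        freqs = 0.02 + 0.88 * rng.beta(0.8, 4.0, size=n_types)
        cfe_spec[name] = CFESpec(cls, dict(zip(types, np.round(freqs, 4))))
    drugs = [f"DRUG{i + 1:02d}" for i in range(n_drugs)]
    baseline = {d: float(np.round(rng.normal(2.0, 1.0), 3)) for d in drugs}
    additive = [AdditiveEffect(drugs[0], "GENE01_mut", -2.0)]
    logic = [LogicEffect(
        drugs[1],
        LogicFormula(((("GENE02_mut", False),), (("RACS01_amp", False),)), "dnf"),
        -2.0,
    )]
    return SimulationConfig(
        cancer_types=cancer_types, cfe_spec=cfe_spec, baseline_ic50=baseline,
        additive_effects=additive, logic_effects=logic, seed=seed,
    )


# ---------------------------------------------------------------------------
# generators


def _simulate_matrix(config: SimulationConfig, counts_idx: int, cohort: str,
                     rng: np.random.Generator) -> AlterationMatrix:
    rows, index, ann_rows = [], [], []
    cfe_ids = list(config.cfe_spec)
    for ctype, counts in config.cancer_types.items():
        n = counts[counts_idx]
        freqs = np.array([config.cfe_spec[c].freq_for(ctype) for c in cfe_ids])
        block = (rng.random((n, len(cfe_ids))) < freqs).astype(float)
        rows.append(block)
        prefix = "T" if cohort == "tumor" else "CL"
        ids = [f"{prefix}_{ctype}_{i + 1:04d}" for i in range(n)]
        index.extend(ids)
        msi = rng.random(n) < config.msi_rate
        for sid, m in zip(ids, msi):
            ann_rows.append((sid, cohort, ctype, "MSI" if m else "MSS"))
    values = pd.DataFrame(np.vstack(rows), index=index, columns=cfe_ids)
    ann = pd.DataFrame(
        ann_rows, columns=["sample_id", "cohort", "cancer_type", "msi"]
    ).set_index("sample_id")
    return AlterationMatrix(values, ann)


def simulate_cohort(config: SimulationConfig):
    """Paired tumor and cell-line cohorts sharing per-type CFE frequencies.

    Returns (tumors, cell_lines, catalog, truth). Deterministic given
    config.seed.
    """
    rng = np.random.default_rng(config.seed)
    tumors = _simulate_matrix(config, 0, "tumor", rng)
    cell_lines = _simulate_matrix(config, 1, "cell_line", rng)
    cfes = [
        CFE(cid, spec.cfe_class, frozenset(config.cancer_types))
        for cid, spec in config.cfe_spec.items()
    ]
    freq = {
        (cid, ctype): config.cfe_spec[cid].freq_for(ctype)
        for cid in config.cfe_spec for ctype in config.cancer_types
    }
    catalog = CFECatalog(cfes, freq, mode="pan_cancer")
    truth = GroundTruth(
        additive_effects=list(config.additive_effects),
        logic_effects=list(config.logic_effects),
        frequencies=pd.DataFrame(
            {cid: {t: config.cfe_spec[cid].freq_for(t)
                   for t in config.cancer_types}
             for cid in config.cfe_spec}
        ),
    )
    return tumors, cell_lines, catalog, truth


def simulate_drug_response(cell_lines: AlterationMatrix,
                           config: SimulationConfig,
                           seed: Optional[int] = None):
    """Planted ln-IC50 responses for every (drug, cell line).

    ln IC50 = baseline + sum(additive beta * CFE indicator)
            + sum(logic beta * formula satisfaction) + N(0, noise_sd).
    The AUC column is filled analytically from the planted ln-IC50 with a
    nominal slope-1 curve over the drug's tested 9-point 2-fold dilution
    range. Returns (DrugResponseTable, GroundTruth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = cell_lines.values
    drugs = list(config.baseline_ic50)
    means = pd.DataFrame(
        {d: np.full(len(X), config.baseline_ic50[d]) for d in drugs},
        index=X.index,
    )
    for eff in config.additive_effects:
        if eff.cfe_id not in X.columns:
            raise ValueError(f"effect references CFE absent from matrix: {eff.cfe_id}")
        means[eff.drug_id] = means[eff.drug_id] + eff.beta * X[eff.cfe_id].fillna(0)
    for eff in config.logic_effects:
        sat = evaluate_formula(eff.formula, X)
        means[eff.drug_id] = means[eff.drug_id] + eff.beta * np.nan_to_num(sat)
    noise = rng.normal(0.0, config.noise_sd, size=means.shape)
    ln_ic50 = means + noise
    max_conc = pd.Series({d: config.max_conc_for(d) for d in drugs})
    auc = pd.DataFrame(index=ln_ic50.index, columns=drugs, dtype=float)
    for d in drugs:
        concs = max_conc[d] / (2.0 ** np.arange(9))
        auc[d] = [compute_auc(v, 1.0, concs) for v in ln_ic50[d]]
    truth = GroundTruth(
        additive_effects=list(config.additive_effects),
        logic_effects=list(config.logic_effects),
        latent_means=means,
    )
    return DrugResponseTable(ln_ic50, auc, max_conc), truth


def simulate_dose_response(responses: DrugResponseTable, n_points: int = 9,
                           dilution: float = 2.0,
                           viability_noise_sd: float = 0.05,
                           seed: int = 0) -> pd.DataFrame:
    """Raw dose-response curves consistent with a response table.

    Per (drug, cell line): a 2-parameter logistic with the table's
    ln-IC50 and a drawn slope (log-normal around 1), evaluated at
    concentrations max_conc / dilution^k, plus Gaussian viability noise
    clipped to [-0.1, 1.2]. Returns a long DataFrame with columns
    drug_id, sample_id, conc_uM, viability.
    """
    if n_points < 5:
        raise ValueError("need n_points >= 5")
    if dilution <= 1:
        raise ValueError("dilution must be > 1")
    rng = np.random.default_rng(seed)
    records = []
    for drug in responses.drug_ids:
        concs = responses.max_conc[drug] / dilution ** np.arange(n_points)
        ln_c = np.log(concs)
        col = responses.ln_ic50[drug].dropna()
        for sample, ln_ic50 in col.items():
            slope = float(np.exp(rng.normal(0.0, 0.25)))
            viab = logistic_viability(ln_c, ln_ic50, slope)
            if viability_noise_sd > 0:
                viab = viab + rng.normal(0, viability_noise_sd, size=viab.shape)
            viab = np.clip(viab, -0.1, 1.2)
            for c, v in zip(concs, viab):
                records.append((drug, sample, c, v))
    return pd.DataFrame(records,
                        columns=["drug_id", "sample_id", "conc_uM", "viability"])


def simulate_methylation(n_samples: int, n_islands: int,
                         informative_fraction: float, seed: int = 0,
                         low_mean: float = 0.1, high_mean: float = 0.8,
                         sd_logit: float = 0.5,
                         cancer_types: Optional[pd.Series] = None):
    """Beta-value tables with a planted fraction of bimodal islands.

    Beta values are logit-normal: informative islands mix a low- and a
    high-methylation component (Gaussians on the logit scale centered at
    logit(low_mean) / logit(high_mean)); the rest are unimodal at a
    low-to-moderate level. Returns (MethylationTable, GroundTruth);
    island_params records the logit-scale component parameters.
    """
    if not (0.0 <= informative_fraction <= 1.0):
        raise ValueError("informative_fraction must be in [0, 1]")
    from scipy.special import expit, logit

    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    islands = [f"ISL{i + 1:04d}" for i in range(n_islands)]
    n_info = int(round(informative_fraction * n_islands))
    flags = np.zeros(n_islands, dtype=bool)
    flags[:n_info] = True

    rows, params = [], []
    for i in range(n_islands):
        if flags[i]:
            w = rng.uniform(0.35, 0.65)
            hi = rng.random(n_samples) < w
            z = np.where(
                hi, rng.normal(logit(high_mean), sd_logit, n_samples),
                rng.normal(logit(low_mean), sd_logit, n_samples),
            )
            betas = expit(z)
            params.append((islands[i], True, float(logit(low_mean)),
                           float(logit(high_mean)), sd_logit, w))
        else:
            mu = logit(rng.uniform(0.1, 0.3))
            betas = expit(rng.normal(mu, sd_logit, n_samples))
            params.append((islands[i], False, float(mu), np.nan, sd_logit,
                           np.nan))
        rows.append(betas)
    betas = pd.DataFrame(np.vstack(rows), index=islands, columns=samples)
    if cancer_types is None:
        cancer_types = pd.Series("CT01", index=samples)
    table = MethylationTable(betas, cancer_types)
    truth = GroundTruth(
        informative_islands=pd.Series(flags, index=islands),
        island_params=pd.DataFrame(
            params,
            columns=["island", "informative", "low_logit_mean",
                     "high_logit_mean", "sd_logit", "high_weight"],
        ).set_index("island"),
    )
    return table, truth


def simulate_expression(annotations: pd.DataFrame, n_genes: int = 50,
                        seed: int = 0) -> pd.DataFrame:
    """Tissue-structured gene-expression matrix (samples x genes).

    Each cancer type gets its own vector of gene means (N(0, 1)); samples
    add unit Gaussian noise. A convenience view for the multi-omic
    prediction scan.
    """
    rng = np.random.default_rng(seed)
    types = sorted(annotations["cancer_type"].unique())
    type_means = {t: rng.normal(0, 1, size=n_genes) for t in types}
    rows = [
        type_means[ct] + rng.normal(0, 1, size=n_genes)
        for ct in annotations["cancer_type"]
    ]
    cols = [f"EXPR{i + 1:04d}" for i in range(n_genes)]
    return pd.DataFrame(np.vstack(rows), index=annotations.index, columns=cols)


def toy_pathway_map(catalog: CFECatalog, n_pathways: int = 13) -> Dict[str, list]:
    """Round-robin assignment of catalog CFEs to toy pathways."""
    pathways: Dict[str, list] = {f"PATHWAY{i + 1:02d}": [] for i in range(n_pathways)}
    keys = list(pathways)
    for i, cid in enumerate(catalog.cfe_ids):
        pathways[keys[i % n_pathways]].append(cid)
    return {k: v for k, v in pathways.items() if v}
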