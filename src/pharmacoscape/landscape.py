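"""Tumor / cell-line concordance and the precision-medicine landscape.

Quantifies how faithfully a cell-line panel recapitulates patient tumors:
per-cancer-type CFE frequency profiles and their correlations, a
nearest-neighbor tissue-of-origin classifier on frequency profiles,
pathway-level alteration-frequency concordance, and a global per-sample
class (M = mutation-dominated, H = hypermethylation, CD = copy-number
deletion, CA = copy-number amplification). Finally, the stratification
landscape reports what fraction of tumors per cancer type carry at least
one sensitivity marker (single CFE or logic rule) for some drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .catalog import CFECatalog
from .logic import LogicFormula, evaluate_formula
from .matrix import AlterationMatrix

GLOBAL_CLASSES = ("M", "H", "CD", "CA")
_CLASS_OF_CFE = {"CG": "M", "iCpG": "H", "RACS_del": "CD", "RACS_amp": "CA"}


@dataclass
class FrequencyProfile:
    cancer_type: str
    cohort: str
    frequencies: pd.Series  # per-CFE alteration frequency in [0, 1]
    n_samples: int


def frequency_profiles(matrix: AlterationMatrix) -> List[FrequencyProfile]:
    """Per (cancer type, cohort) CFE frequency profiles.

    Frequencies are column means over non-missing entries; empty groups
    are skipped.
    """
    profiles = []
    ann = matrix.annotations
    for (ctype, cohort), idx in ann.groupby(
            ["cancer_type", "cohort"], observed=True).groups.items():
        sub = matrix.values.loc[idx]
        if len(sub) == 0:
            continue
        profiles.append(FrequencyProfile(ctype, cohort, sub.mean(axis=0),
                                         len(sub)))
    return profiles


def profile_correlation(profiles_a: List[FrequencyProfile],
                        profiles_b: List[FrequencyProfile]) -> pd.DataFrame:
    """Pearson correlation between every pair of profiles over shared CFEs.

    Zero-variance profiles yield NaN for their pairs.
    """
    corr = pd.DataFrame(
        index=[p.cancer_type for p in profiles_a],
        columns=[p.cancer_type for p in profiles_b], dtype=float,
    )
    for pa in profiles_a:
        for pb in profiles_b:
            shared = pa.frequencies.index.intersection(pb.frequencies.index)
            a = pa.frequencies.loc[shared].to_numpy()
            b = pb.frequencies.loc[shared].to_numpy()
            if a.std() == 0 or b.std() == 0 or len(shared) < 3:
                continue
            corr.loc[pa.cancer_type, pb.cancer_type] = float(np.corrcoef(a, b)[0, 1])
    return corr


def nn_tissue_match(cell_profiles: List[FrequencyProfile],
                    tumor_profiles: List[FrequencyProfile],
                    k: int = 1) -> Tuple[float, pd.DataFrame]:
    """Nearest-neighbor tissue-of-origin matching, pooled over directions.

    Each cell-line profile ranks all tumor profiles by correlation
    distance (1 - Pearson r) and is correct when a profile of its own
    cancer type appears within the top k; likewise tumor -> cell line.
    Accuracy pools both directions. Returns (top-k accuracy, match table
    with the rank of the true cancer type per query).
    """
    if len({p.cancer_type for p in cell_profiles}) < 2 or \
            len({p.cancer_type for p in tumor_profiles}) < 2:
        raise ValueError("need >= 2 cancer types per cohort")
    rows = []
    for queries, refs, direction in (
        (cell_profiles, tumor_profiles, "cell_to_tumor"),
        (tumor_profiles, cell_profiles, "tumor_to_cell"),
    ):
        corr = profile_correlation(queries, refs)
        for q in queries:
            sims = corr.loc[q.cancer_type].dropna()
            if q.cancer_type not in sims.index or len(sims) < 2:
                continue  # missing correlations: pair excluded
            ranked = sims.sort_values(ascending=False)
            rank = int(np.flatnonzero(ranked.index == q.cancer_type)[0]) + 1
            rows.append((direction, q.cancer_type, rank))
    table = pd.DataFrame(rows, columns=["direction", "cancer_type", "true_rank"])
    return topk_accuracy(table, k), table


def topk_accuracy(match_table: pd.DataFrame, k: int) -> float:
    """Fraction of queries whose true cancer type ranks within the top k."""
    if len(match_table) == 0:
        return np.nan
    return float((match_table["true_rank"] <= k).mean())


def pathway_frequency_correlation(tumors: AlterationMatrix,
                                  cell_lines: AlterationMatrix,
                                  pathway_map: Dict[str, Iterable[str]]
                                  ) -> Tuple[pd.Series, float]:
    """Per-pathway correlation of alteration fractions across cancer types.

    A sample counts as pathway-altered when at least one mapped CFE is
    altered. For each pathway, the per-cancer-type altered fractions in
    tumors and cell lines are correlated (Pearson across cancer types).
    Returns (per-pathway R, median R).
    """
    if not pathway_map:
        raise ValueError("pathway_map is empty")
    types = sorted(
        set(tumors.annotations["cancer_type"])
        & set(cell_lines.annotations["cancer_type"])
    )
    result = {}
    for pathway, cfes in pathway_map.items():
        cfes = [c for c in cfes if c in tumors.values.columns
                and c in cell_lines.values.columns]
        if not cfes:
            result[pathway] = np.nan
            continue
        fr_t, fr_c = [], []
        for ct in types:
            t = tumors.by_cancer_type(ct).values[cfes]
            c = cell_lines.by_cancer_type(ct).values[cfes]
            fr_t.append(float((t.fillna(0).max(axis=1) == 1).mean()))
            fr_c.append(float((c.fillna(0).max(axis=1) == 1).mean()))
        fr_t, fr_c = np.array(fr_t), np.array(fr_c)
        if fr_t.std() == 0 or fr_c.std() == 0:
            result[pathway] = np.nan
        else:
            result[pathway] = float(np.corrcoef(fr_t, fr_c)[0, 1])
    per_pathway = pd.Series(result)
    return per_pathway, float(per_pathway.median())


@dataclass
class GlobalClassAssignment:
    sample_id: str
    global_class: Optional[str]  # None = unclassified (no alterations)
    burden: pd.Series            # normalized burden per class


def assign_global_classes(matrix: AlterationMatrix, catalog: CFECatalog
                          ) -> List[GlobalClassAssignment]:
    """Dominant-alteration-class assignment per sample.

    A sample's burden for each class (M/H/CD/CA) is its count of altered
    CFEs of the corresponding CFE type divided by the cohort-wide mean
    count for that type; the sample is assigned the argmax class, ties
    broken by the fixed priority M > H > CD > CA. Samples with zero burden
    everywhere are unclassified.
    """
    classes = catalog.classes()
    cols_by_class = {g: [] for g in GLOBAL_CLASSES}
    for cfe_id in matrix.values.columns:
        g = _CLASS_OF_CFE.get(classes.get(cfe_id, ""))
        if g:
            cols_by_class[g].append(cfe_id)
    counts = pd.DataFrame(index=matrix.values.index, columns=GLOBAL_CLASSES,
                          dtype=float)
    for g, cols in cols_by_class.items():
        counts[g] = (matrix.values[cols].fillna(0).sum(axis=1)
                     if cols else 0.0)
    means = counts.mean(axis=0).replace(0.0, np.nan)
    burden = counts / means
    assignments = []
    for sid in matrix.values.index:
        row = burden.loc[sid].fillna(0.0)
        if counts.loc[sid].sum() == 0:
            assignments.append(GlobalClassAssignment(sid, None, row))
            continue
        best = max(GLOBAL_CLASSES,
                   key=lambda g: (row[g], -GLOBAL_CLASSES.index(g)))
        assignments.append(GlobalClassAssignment(sid, best, row))
    return assignments


def _modal_class(assignments: List[GlobalClassAssignment]) -> Optional[str]:
    counts = {g: 0 for g in GLOBAL_CLASSES}
    for a in assignments:
        if a.global_class:
            counts[a.global_class] += 1
    if not any(counts.values()):
        return None
    return max(GLOBAL_CLASSES, key=lambda g: (counts[g], -GLOBAL_CLASSES.index(g)))


def class_concordance(tumor_assignments: List[GlobalClassAssignment],
                      cell_assignments: List[GlobalClassAssignment],
                      tumor_annotations: pd.DataFrame,
                      cell_annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-cancer-type concordance of predominant global classes.

    The predominant (modal) class per cohort and cancer type is compared;
    concordant iff equal. Modal ties follow the M > H > CD > CA priority.
    """
    t_by = {sid: a for sid, a in
            zip([a.sample_id for a in tumor_assignments], tumor_assignments)}
    c_by = {sid: a for sid, a in
            zip([a.sample_id for a in cell_assignments], cell_assignments)}
    types = sorted(
        set(tumor_annotations["cancer_type"]) & set(cell_annotations["cancer_type"])
    )
    rows = []
    for ct in types:
        t_ids = tumor_annotations.index[tumor_annotations["cancer_type"] == ct]
        c_ids = cell_annotations.index[cell_annotations["cancer_type"] == ct]
        tm = _modal_class([t_by[s] for s in t_ids if s in t_by])
        cm = _modal_class([c_by[s] for s in c_ids if s in c_by])
        if tm is None or cm is None:
            continue
        rows.append((ct, tm, cm, tm == cm))
    return pd.DataFrame(
        rows, columns=["cancer_type", "tumor_class", "cell_class", "concordant"])


@dataclass
class StratificationRow:
    cancer_type: str
    percent: float              # % of tumors carrying >= 1 sensitivity marker
    marker_kind: str            # "single_cfe" or "logic"
    contributing_markers: List[str]


def stratification_landscape(tumors: AlterationMatrix,
                             single_markers: Optional[Iterable[str]] = None,
                             logic_markers: Optional[Iterable[LogicFormula]] = None
                             ) -> List[StratificationRow]:
    """Percent of tumor samples per cancer type carrying a sensitivity marker.

    Single-CFE markers count a sample when the CFE is altered; logic
    markers when the sample satisfies the formula. Markers referencing
    CFEs absent from the tumor matrix are skipped. Percentages are
    reported separately for single-CFE and logic markers.
    """
    single_markers = list(single_markers or [])
    logic_markers = list(logic_markers or [])
    rows = []
    for ct in sorted(tumors.annotations["cancer_type"].unique()):
        sub = tumors.by_cancer_type(ct).values
        present = [m for m in single_markers if m in sub.columns]
        hit = (sub[present].fillna(0) == 1).any(axis=1) if present else \
            pd.Series(False, index=sub.index)
        rows.append(StratificationRow(
            ct, float(100.0 * hit.mean()), "single_cfe", present))
        usable = []
        sat = pd.Series(False, index=sub.index)
        for formula in logic_markers:
            if any(f not in sub.columns for f in formula.features):
                continue
            usable.append(str(formula))
            sat = sat | (evaluate_formula(formula, sub) == 1.0)
        rows.append(StratificationRow(
            ct, float(100.0 * sat.mean()), "logic", usable))
    return rows
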