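"""Binary alteration matrices (samples x CFEs) with sample annotations.

The alteration matrix is the universal feature object of the pipeline:
rows are samples (patient tumors or cell lines), columns are CFEs, entries
are 0/1 with missing allowed. Annotations carry cohort (tumor vs cell
line), a TCGA-style cancer-type label and microsatellite-instability
status per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .catalog import CFECatalog

COHORTS = ("tumor", "cell_line")
MSI_LEVELS = ("MSI", "MSS", "unknown")
ANNOTATION_COLUMNS = ["sample_id", "cohort", "cancer_type", "msi"]


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    cohort: str
    cancer_type: str
    msi: str = "unknown"

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if not self.cancer_type:
            raise ValueError("cancer_type must be non-empty")
        if self.msi not in MSI_LEVELS:
            raise ValueError(f"msi must be one of {MSI_LEVELS}, got {self.msi!r}")


class AlterationMatrix:
    """Samples x CFEs binary matrix with per-sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Index = sample ids, columns = CFE ids, entries in {0, 1, NaN}.
    annotations : pandas.DataFrame
        Indexed by sample id with columns cohort, cancer_type, msi;
        must cover every sample of `values`.
    """

    def __init__(self, values: pd.DataFrame, annotations: pd.DataFrame):
        values = values.astype(float)
        bad = ~(values.isna() | values.isin([0.0, 1.0]))
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"entry at sample {values.index[r]!r}, CFE {values.columns[c]!r} "
                f"is {values.iat[r, c]!r}; expected 0, 1 or NA"
            )
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("duplicate sample or CFE ids")
        missing = values.index.difference(annotations.index)
        if len(missing):
            raise ValueError(f"samples without annotation: {list(missing)[:5]}")
        values.index.name = "sample_id"
        values.columns.name = None
        self.values = values
        self.annotations = annotations.loc[values.index, ["cohort", "cancer_type", "msi"]]
        self.annotations.index.name = "sample_id"
        for ann in self.annotations.itertuples():
            SampleAnnotation(ann.Index, ann.cohort, ann.cancer_type, ann.msi)

    # -- basic interface ---------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def cfe_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self):
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "AlterationMatrix":
        ids = list(sample_ids)
        return AlterationMatrix(self.values.loc[ids], self.annotations.loc[ids])

    def by_cancer_type(self, cancer_type: str) -> "AlterationMatrix":
        mask = self.annotations["cancer_type"] == cancer_type
        return self.subset_samples(self.annotations.index[mask])

    # -- I/O ---------------------------------------------------------------

    def write_tsv(self, path, annotation_path):
        self.values.to_csv(path, sep="\t", na_rep="NA")
        self.annotations.to_csv(annotation_path, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return ann.set_index("sample_id")


def read_alteration_matrix(path, annotation_path) -> AlterationMatrix:
    """Read a 0/1/NA TSV matrix plus its annotation table.

    The matrix TSV has a header row of CFE ids and sample ids in the first
    column. Entries other than 0/1/NA raise a parse error naming the
    offending row and column; samples absent from the annotation table are
    rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for sid, entry in raw[col].items():
            if entry in ("NA", "", "nan", "NaN"):
                values.at[sid, col] = np.nan
            elif entry in ("0", "0.0"):
                values.at[sid, col] = 0.0
            elif entry in ("1", "1.0"):
                values.at[sid, col] = 1.0
            else:
                raise ValueError(
                    f"malformed entry {entry!r} at sample {sid!r}, CFE {col!r} "
                    f"in {path}: expected 0, 1 or NA"
                )
    annotations = read_annotations(annotation_path)
    return AlterationMatrix(values, annotations)


@dataclass
class CoverageReport:
    """Which catalog CFEs the cell-line matrix actually covers."""

    absent_cfes: list
    n_catalog: int

    @property
    def coverage(self) -> float:
        if self.n_catalog == 0:
            return 0.0
        return 1.0 - len(self.absent_cfes) / self.n_catalog


def filter_by_catalog(matrix: AlterationMatrix, catalog: CFECatalog,
                      drop_absent: bool = False):
    """Restrict a cell-line alteration matrix to the tumor-derived catalog.

    Columns are restricted to (and ordered by) the catalog's CFE ids.
    Catalog CFEs absent from the matrix become all-zero columns and are
    listed in the coverage report; with ``drop_absent`` they are dropped
    instead.

    Returns
    -------
    (AlterationMatrix, CoverageReport)
    """
    import warnings

    present = [c for c in catalog.cfe_ids if c in matrix.values.columns]
    absent = [c for c in catalog.cfe_ids if c not in matrix.values.columns]
    if not present:
        warnings.warn("no overlap between matrix CFEs and catalog", stacklevel=2)
    sub = matrix.values.reindex(columns=catalog.cfe_ids, fill_value=0.0)
    if drop_absent:
        sub = sub[present]
    return AlterationMatrix(sub, matrix.annotations), CoverageReport(
        absent_cfes=absent, n_catalog=len(catalog)
    )
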