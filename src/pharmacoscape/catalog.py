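"""Cancer functional event (CFE) catalogs.

A CFE is a binarized, clinically relevant molecular alteration observed in
patient tumors: a driver-gene mutation (CG), a recurrently aberrant copy
number segment (RACS, amplified or deleted), a hypermethylated informative
CpG island (iCpG), a gene fusion, or a binarized pathway-activity call.
A catalog lists CFEs together with their per-cancer-type frequency in the
tumor cohort, and is the filter applied to cell-line alteration matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

CFE_CLASSES = ("CG", "RACS_amp", "RACS_del", "iCpG", "fusion", "pathway_activity")


@dataclass(frozen=True)
class CFE:
    """One cancer functional event."""

    id: str
    cfe_class: str
    cancer_types: frozenset = field(default_factory=frozenset)
    locus_label: Optional[str] = None

    def __post_init__(self):
        if self.cfe_class not in CFE_CLASSES:
            raise ValueError(
                f"cfe_class {self.cfe_class!r} not one of {CFE_CLASSES}"
            )
        object.__setattr__(self, "cancer_types", frozenset(self.cancer_types))


class CFECatalog:
    """A list of CFEs with per-(CFE, cancer type) tumor frequencies.

    Parameters
    ----------
    cfes : iterable of CFE
        Unique ids required.
    frequency : mapping (cfe_id, cancer_type) -> float in [0, 1]
        Tumor alteration frequency.
    mode : {"pan_cancer", "cancer_specific"}
    """

    def __init__(self, cfes: Iterable[CFE], frequency: Mapping = None,
                 mode: str = "cancer_specific"):
        self.cfes = list(cfes)
        self.frequency = dict(frequency or {})
        if mode not in ("pan_cancer", "cancer_specific"):
            raise ValueError(f"invalid catalog mode {mode!r}")
        self.mode = mode
        self._validate()

    def _validate(self):
        ids = [c.id for c in self.cfes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate CFE ids in catalog: {dup}")
        known = set(ids)
        for (cfe_id, ctype), f in self.frequency.items():
            if cfe_id not in known:
                raise ValueError(f"frequency key references unknown CFE {cfe_id!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"frequency for ({cfe_id}, {ctype}) = {f} outside [0, 1]"
                )

    @property
    def cfe_ids(self) -> list:
        return [c.id for c in self.cfes]

    def __len__(self):
        return len(self.cfes)

    def __contains__(self, cfe_id):
        return cfe_id in set(self.cfe_ids)

    def get(self, cfe_id: str) -> CFE:
        for c in self.cfes:
            if c.id == cfe_id:
                return c
        raise KeyError(cfe_id)

    def classes(self) -> dict:
        """Map cfe_id -> cfe_class."""
        return {c.id: c.cfe_class for c in self.cfes}

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        ctypes = sorted({ct for (_, ct) in self.frequency})
        rows = []
        for c in self.cfes:
            row = {
                "cfe_id": c.id,
                "cfe_class": c.cfe_class,
                "cancer_types": ",".join(sorted(c.cancer_types)),
            }
            for ct in ctypes:
                row[f"freq_{ct}"] = self.frequency.get((c.id, ct), float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str = "cancer_specific"):
        cfes, freq = [], {}
        freq_cols = [c for c in df.columns if c.startswith("freq_")]
        for _, row in df.iterrows():
            raw = row.get("cancer_types", "")
            ctypes = frozenset(t for t in str(raw).split(",") if t and t != "nan")
            cfes.append(CFE(row["cfe_id"], row["cfe_class"], ctypes))
            for col in freq_cols:
                f = row[col]
                if pd.notna(f):
                    freq[(row["cfe_id"], col[len("freq_"):])] = float(f)
        return cls(cfes, freq, mode=mode)

    @classmethod
    def read_tsv(cls, path, mode: str = "cancer_specific"):
        return cls.from_frame(pd.read_csv(path, sep="\t"), mode=mode)


def merge_catalogs(catalogs: Iterable[CFECatalog]) -> CFECatalog:
    """Merge cancer-specific catalogs into one pan-cancer catalog.

    CFE ids are deduplicated, cancer-type sets unioned and per-(id, cancer
    type) frequencies retained. A CFE id appearing with conflicting classes
    is a consistency error. Merging is idempotent: feeding a merged
    catalog back in changes nothing.
    """
    catalogs = list(catalogs)
    if not catalogs:
        raise ValueError("no catalogs to merge")
    by_id: dict = {}
    freq: dict = {}
    for cat in catalogs:
        for c in cat.cfes:
            if c.id in by_id:
                prev = by_id[c.id]
                if prev.cfe_class != c.cfe_class:
                    raise ValueError(
                        f"CFE {c.id!r} has conflicting classes "
                        f"{prev.cfe_class!r} vs {c.cfe_class!r}"
                    )
                by_id[c.id] = CFE(
                    c.id, c.cfe_class,
                    prev.cancer_types | c.cancer_types,
                    prev.locus_label or c.locus_label,
                )
            else:
                by_id[c.id] = c
        freq.update(cat.frequency)
    return CFECatalog(by_id.values(), freq, mode="pan_cancer")
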