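"""Count-matrix data model, TSV I/O and the discovery-phase low-count filter.

The count matrix holds the number of sequencing reads unambiguously assigned
to each mature miRNA (rows) in each urine sample (columns).  The cohort
metadata carries the per-sample class label (healthy control or one of three
bladder-cancer subtypes ordered by severity), the adjustment covariates age
and smoking status, and an optional processing-batch label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered class labels: healthy controls, then bladder-cancer subtypes by
#: increasing invasiveness/grade.  The order defines the ordinal score used
#: by the trend test.
CLASS_LEVELS = ("control", "NMIBC_G1G2", "NMIBC_G3", "MIBC")
SMOKING_LEVELS = ("never", "former", "current")

AGE_PLAUSIBLE = (30.0, 100.0)


class ParseError(ValueError):
    """A table failed validation; the message names the offending row/column."""


@dataclass
class CountMatrix:
    """Integer read counts, miRNA x sample.

    Parameters
    ----------
    data
        DataFrame indexed by miRNA id with one column per sample id.
        Values must be non-negative integers; ids must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicate miRNA id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))
                i, j = bad[0]
                raise ParseError(
                    f"non-integer count at miRNA {df.index[i]!r}, sample {df.columns[j]!r}"
                )
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            i, j = np.argwhere(df.to_numpy() < 0)[0]
            raise ParseError(
                f"negative count at miRNA {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.data = df

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """miRNA x sample integer array."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing}")
        return CountMatrix(self.data.loc[:, sample_ids])

    def row(self, mirna_id: str) -> np.ndarray:
        if mirna_id not in self.data.index:
            raise KeyError(f"unknown miRNA id {mirna_id!r}")
        return self.data.loc[mirna_id].to_numpy()


@dataclass
class CohortMetadata:
    """Per-sample class label, age, smoking status and optional batch.

    ``data`` is indexed by sample id with columns ``class``, ``age``,
    ``smoking`` and optionally ``batch``.
    """

    data: pd.DataFrame
    normalize_case: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        required = {"class", "age", "smoking"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"metadata missing column(s) {sorted(missing)}")
        if self.normalize_case:
            lut = {lvl.lower(): lvl for lvl in CLASS_LEVELS}
            df["class"] = [lut.get(str(c).lower(), c) for c in df["class"]]
            slut = {lvl.lower(): lvl for lvl in SMOKING_LEVELS}
            df["smoking"] = [slut.get(str(s).lower(), s) for s in df["smoking"]]
        for sid, c in df["class"].items():
            if c not in CLASS_LEVELS:
                raise ParseError(f"unknown class {c!r} for sample {sid!r}")
        for sid, s in df["smoking"].items():
            if s not in SMOKING_LEVELS:
                raise ParseError(f"unknown smoking level {s!r} for sample {sid!r}")
        ages = pd.to_numeric(df["age"], errors="raise")
        out_of_range = (ages < AGE_PLAUSIBLE[0]) | (ages > AGE_PLAUSIBLE[1])
        if out_of_range.any():
            warnings.warn(
                f"{int(out_of_range.sum())} sample(s) with age outside "
                f"{AGE_PLAUSIBLE}; check units",
                stacklevel=2,
            )
        df["age"] = ages.astype(float)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def classes(self) -> pd.Series:
        return self.data["class"]

    def aligned_to(self, m: CountMatrix) -> "CohortMetadata":
        """Reorder to the count matrix's samples; every sample must be present."""
        missing = [s for s in m.sample_ids if s not in self.data.index]
        if missing:
            raise ParseError(f"metadata missing sample(s) {missing}")
        return CohortMetadata(self.data.loc[m.sample_ids])

    def subset(self, sample_ids: list[str]) -> "CohortMetadata":
        return CohortMetadata(self.data.loc[sample_ids])


def read_counts(path) -> CountMatrix:
    """Read a tab-separated count matrix (first column = miRNA id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(m: CountMatrix, path) -> None:
    m.data.rename_axis("mirna_id").to_csv(path, sep="\t")


def read_metadata(path, normalize_case: bool = False) -> CohortMetadata:
    """Read a tab-separated metadata table with a ``sample_id`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"batch": str})
    if "sample_id" not in df.columns:
        raise ParseError("metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return CohortMetadata(df, normalize_case=normalize_case)


def write_metadata(meta: CohortMetadata, path) -> None:
    meta.data.rename_axis("sample_id").to_csv(path, sep="\t")


def filter_low_counts(m: CountMatrix, min_total: int = 20) -> CountMatrix:
    """Keep miRNAs with at least ``min_total`` reads summed over all samples.

    The boundary is inclusive and row order is preserved.  The default of 20
    is the discovery-phase detection filter for urinary small RNA-seq.
    """
    totals = m.data.sum(axis=1)
    return CountMatrix(m.data.loc[totals >= min_total])


def mean_read_count(m: CountMatrix, mirna_id: str) -> float:
    """Arithmetic mean of raw counts across all samples for one miRNA."""
    return float(m.row(mirna_id).mean())
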