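"""Samples x CpG-sites methylation matrix with per-sample metadata.

The matrix lives on a continuous normalized (M-value-like) scale; rows are
samples, columns are CpG sites.  Metadata carries per-sample age (years),
group label and train/test split assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

YOUNG = "young"
CONTROL = "control"
DISEASES = ("AD", "PD", "PSP", "FTD")
GROUPS = (YOUNG, CONTROL) + DISEASES

SPLIT_TRAIN = "train"
SPLIT_TEST = "test"
SPLIT_UNASSIGNED = "unassigned"

_META_COLUMNS = ("age", "group", "split")


@dataclass
class MethylationDataset:
    """A samples x sites value matrix plus aligned per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per CpG id.  May
        contain NaN before imputation.
    meta
        DataFrame indexed by sample id with columns ``age`` (float years,
        NaN if unknown), ``group`` (one of :data:`GROUPS`) and ``split``
        (``train``/``test``/``unassigned``).
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same sample index")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate CpG site ids")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [c for c in _META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta lacks columns: {missing}")
        bad = set(self.meta["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    # -- convenience views ------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def age(self) -> pd.Series:
        return self.meta["age"]

    @property
    def group(self) -> pd.Series:
        return self.meta["group"]

    @property
    def split(self) -> pd.Series:
        return self.meta["split"]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    # -- subsetting -------------------------------------------------------
    def select_samples(self, mask) -> "MethylationDataset":
        """Row subset by boolean mask or list of sample ids."""
        if isinstance(mask, (list, tuple, pd.Index, np.ndarray)) and not (
            isinstance(mask, np.ndarray) and mask.dtype == bool
        ):
            return MethylationDataset(self.values.loc[mask], self.meta.loc[mask])
        mask = np.asarray(mask, dtype=bool)
        return MethylationDataset(self.values.loc[mask], self.meta.loc[mask])

    def select_sites(self, site_ids) -> "MethylationDataset":
        return MethylationDataset(self.values[list(site_ids)], self.meta)

    def group_mask(self, *groups: str) -> np.ndarray:
        return self.meta["group"].isin(groups).to_numpy()

    def with_values(self, values: pd.DataFrame) -> "MethylationDataset":
        return MethylationDataset(values, self.meta.loc[values.index].copy())

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(self.values.copy(), self.meta.copy())

    # -- I/O ----------------------------------------------------------------
    def to_files(self, matrix_path, meta_path, sep: str = "\t") -> None:
        """Write the matrix (rows = samples, columns = CpG ids) and metadata."""
        self.values.to_csv(matrix_path, sep=sep, index_label="sample_id")
        self.meta.to_csv(meta_path, sep=sep, index_label="sample_id")

    @classmethod
    def from_files(cls, matrix_path, meta_path, sep: str = "\t") -> "MethylationDataset":
        values = pd.read_csv(matrix_path, sep=sep, index_col="sample_id")
        meta = pd.read_csv(meta_path, sep=sep, index_col="sample_id")
        meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
        return cls(values, meta.loc[values.index])


def make_meta(sample_ids, age, group, split=None) -> pd.DataFrame:
    """Assemble a metadata frame with the canonical columns."""
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "age": np.asarray(age, dtype=float),
            "group": list(group),
            "split": list(split) if split is not None else [SPLIT_UNASSIGNED] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
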