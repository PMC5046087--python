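"""Core containers for CE-MS feature data.

A *feature* is an (m/z, migration time) pair; its intensity (peak height)
is the abundance proxy. Zero intensities are treated as missing throughout,
so every container encodes missing as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: decimals used when rendering feature ids ("<mz>/<mt>")
MZ_DECIMALS = 6
MT_DECIMALS = 3


@dataclass(frozen=True)
class FeatureKey:
    """Identity of a molecule feature: m/z (Th) and migration time (s)."""

    mz: float
    mt: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValueError(f"mz must be positive, got {self.mz}")
        if not (self.mt > 0):
            raise ValueError(f"mt must be positive, got {self.mt}")

    @property
    def id(self) -> str:
        return f"{self.mz:.{MZ_DECIMALS}f}/{self.mt:.{MT_DECIMALS}f}"

    @classmethod
    def from_id(cls, fid: str) -> "FeatureKey":
        mz_s, mt_s = fid.split("/")
        return cls(mz=float(mz_s), mt=float(mt_s))


class PeakList:
    """One CE-MS run's peak table: columns ``mz``, ``mt``, ``intensity``.

    Zero intensities are converted to NaN on construction ("missing").
    Duplicate feature ids within one run are rejected.
    """

    def __init__(
        self,
        sample_id: str,
        table: pd.DataFrame,
        acquired_at: Optional[str] = None,
    ) -> None:
        required = {"mz", "mt", "intensity"}
        if not required.issubset(table.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        tab = table.loc[:, ["mz", "mt", "intensity"]].reset_index(drop=True).copy()
        tab["intensity"] = tab["intensity"].astype(float).replace(0.0, np.nan)
        ids = [FeatureKey(r.mz, r.mt).id for r in tab.itertuples()]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate feature ids in sample {sample_id!r}")
        tab.index = pd.Index(ids, name="feature_id")
        self.sample_id = sample_id
        self.table = tab
        self.acquired_at = acquired_at

    def __len__(self) -> int:
        return len(self.table)

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index

    def keys(self) -> list[FeatureKey]:
        return [FeatureKey(r.mz, r.mt) for r in self.table.itertuples()]

    def copy(self) -> "PeakList":
        pl = PeakList.__new__(PeakList)
        pl.sample_id = self.sample_id
        pl.table = self.table.copy()
        pl.acquired_at = self.acquired_at
        return pl

    def with_mt(self, mt: np.ndarray) -> "PeakList":
        """Copy with migration times replaced.

        Feature ids (the index) are kept from the original observation so
        that cross-references survive alignment.
        """
        pl = self.copy()
        pl.table["mt"] = np.asarray(mt, dtype=float)
        return pl

    def with_intensity(self, intensity: np.ndarray) -> "PeakList":
        pl = self.copy()
        vals = np.asarray(intensity, dtype=float)
        pl.table["intensity"] = np.where(vals == 0.0, np.nan, vals)
        return pl

    def subset(self, feature_ids: Iterable[str]) -> "PeakList":
        pl = self.copy()
        pl.table = pl.table.loc[list(feature_ids)]
        return pl


class FeatureMatrix:
    """Features x samples intensity matrix with NaN for missing values.

    ``values`` is a DataFrame indexed by feature id strings ("mz/mt"),
    columns are sample ids. ``groups`` is an optional sample -> label map.
    """

    def __init__(self, values: pd.DataFrame,
                 groups: Optional[pd.Series] = None) -> None:
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("matrix must have >=1 feature and >=1 sample")
        if values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = values.astype(float).replace(0.0, np.nan)
        if groups is not None:
            groups = pd.Series(groups).reindex(values.columns)
            if groups.isna().any():
                raise ValueError("groups must label every sample")
        self.groups = groups

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def mz_array(self) -> np.ndarray:
        return np.array([FeatureKey.from_id(i).mz for i in self.values.index])

    def mt_array(self) -> np.ndarray:
        return np.array([FeatureKey.from_id(i).mt for i in self.values.index])

    def log2(self) -> pd.DataFrame:
        """Log2 intensities (NaN preserved)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.log2(self.values)

    def subset_features(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(ids)], groups=self.groups)

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        g = self.groups.loc[list(ids)] if self.groups is not None else None
        return FeatureMatrix(self.values.loc[:, list(ids)], groups=g)

    def group_columns(self) -> dict[str, list[str]]:
        if self.groups is None:
            raise ValueError("matrix has no group labels")
        out: dict[str, list[str]] = {}
        for sid, lab in self.groups.items():
            out.setdefault(str(lab), []).append(sid)
        return out

    def copy(self) -> "FeatureMatrix":
        g = self.groups.copy() if self.groups is not None else None
        return FeatureMatrix(self.values.copy(), groups=g)


@dataclass
class ReferenceDataset:
    """Consensus feature matrix plus the ordered stable-feature set.

    ``stable`` lists feature ids in ascending selection-score order; they are
    the internal standards used for migration-time and intensity
    normalization of new samples.
    """

    matrix: FeatureMatrix
    stable: list[str] = field(default_factory=list)
    mt_window: tuple[float, float] = (520.0, 3650.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.stable) - set(self.matrix.feature_ids)
        if missing:
            raise ValueError(f"stable features not in matrix: {sorted(missing)[:5]}")

    @property
    def stable_median_log2(self) -> pd.Series:
        """Reference abundance of each standard: median log2 across runs."""
        return self.matrix.log2().loc[self.stable].median(axis=1, skipna=True)
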