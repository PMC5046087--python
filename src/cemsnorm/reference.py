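"""Building the reference dataset from a collection of peak lists.

The reference is the consensus feature matrix against which every new
sample is later matched and normalized: runs are window-filtered on
migration time, features are grouped across runs by (m/z, MT) proximity,
and only features present in at least a minimum fraction of runs are kept.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import FeatureKey, FeatureMatrix, PeakList, ReferenceDataset

log = logging.getLogger(__name__)

#: cross-run grouping defaults: mz mirrors the mass-match tolerance,
#: mt mirrors the upstream peak-grouping bandwidth (seconds)
DEFAULT_MZ_TOL = 0.01
DEFAULT_MT_TOL = 20.0


def filter_mt_window(pl: PeakList, lo: float, hi: float) -> PeakList:
    """Keep features with migration time in [lo, hi] seconds (inclusive)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    mask = (pl.table["mt"] >= lo) & (pl.table["mt"] <= hi)
    if not mask.any():
        log.warning("sample %s: no features left in MT window (%g, %g)",
                    pl.sample_id, lo, hi)
    out = pl.copy()
    out.table = pl.table.loc[mask].copy()  # feature ids preserved
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def assemble_matrix(pls: Sequence[PeakList],
                    mz_tol: float = DEFAULT_MZ_TOL,
                    mt_tol: float = DEFAULT_MT_TOL) -> FeatureMatrix:
    """Group features across runs and build the intensity matrix.

    Two records are linked when |dmz| <= mz_tol and |dmt| <= mt_tol;
    connected components (single linkage) become one consensus feature,
    keyed by the centroid (mean m/z, mean MT) of its members. When one
    sample contributes several records to a group, the maximum intensity
    wins (peak height is the abundance proxy).
    """
    if len(pls) < 2:
        raise ValueError("need at least two peak lists")
    sample_ids = [pl.sample_id for pl in pls]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    recs = []
    for pl in pls:
        for r in pl.table.itertuples():
            recs.append((r.mz, r.mt, r.intensity, pl.sample_id))
    if not recs:
        raise ValueError("all peak lists are empty")
    mz = np.array([r[0] for r in recs])
    mt = np.array([r[1] for r in recs])
    order = np.lexsort((mt, mz))

    uf = _UnionFind(len(recs))
    # sorted by mz: only a short forward window can satisfy |dmz| <= tol
    for a in range(len(order)):
        i = order[a]
        for b in range(a + 1, len(order)):
            j = order[b]
            if mz[j] - mz[i] > mz_tol:
                break
            if abs(mt[j] - mt[i]) <= mt_tol:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(recs)):
        groups.setdefault(uf.find(i), []).append(i)

    rows = {}
    for members in groups.values():
        key = FeatureKey(mz=float(np.mean(mz[members])),
                         mt=float(np.mean(mt[members])))
        vals: dict[str, float] = {}
        for i in members:
            _, _, inten, sid = recs[i]
            if sid in vals:
                log.warning("sample %s: multiple records in feature group %s; "
                            "keeping max intensity", sid, key.id)
                vals[sid] = np.nanmax([vals[sid], inten])
            else:
                vals[sid] = inten
        rows[key.id] = vals

    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat = mat.reindex(columns=sample_ids)
    mat = mat.sort_index()
    return FeatureMatrix(mat)


def filter_by_presence(fm: FeatureMatrix, min_fraction: float) -> FeatureMatrix:
    """Keep features with non-missing fraction >= min_fraction (inclusive)."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = fm.values.notna().sum(axis=1) / fm.n_samples
    keep = frac[frac >= min_fraction].index
    if len(keep) == 0:
        raise ValueError("presence filter removed every feature")
    return FeatureMatrix(fm.values.loc[keep], groups=fm.groups)


def build_reference(pls: Sequence[PeakList],
                    mt_lo: float = 520.0, mt_hi: float = 3650.0,
                    min_presence: float = 0.5,
                    mz_tol: float = DEFAULT_MZ_TOL,
                    mt_tol: float = DEFAULT_MT_TOL,
                    groups: Optional[pd.Series] = None,
                    provenance: Optional[dict] = None) -> ReferenceDataset:
    """End-to-end reference construction: window filter, cross-run grouping,
    presence filter. The stable set is left empty (see stable_selection)."""
    filtered = [filter_mt_window(pl, mt_lo, mt_hi) for pl in pls]
    fm = assemble_matrix(filtered, mz_tol=mz_tol, mt_tol=mt_tol)
    fm = filter_by_presence(fm, min_presence)
    if groups is not None:
        fm = FeatureMatrix(fm.values, groups=groups)
    prov = dict(provenance or {})
    prov.setdefault("n_runs", len(pls))
    prov.setdefault("min_presence", min_presence)
    # upstream peak-picking provenance, recorded as metadata only
    prov.setdefault("upstream", {"peak_picking": "xcms", "steps": 3, "bw": 20})
    return ReferenceDataset(matrix=fm, stable=[], mt_window=(mt_lo, mt_hi),
                            provenance=prov)
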