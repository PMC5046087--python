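"""Processing a new sample against the reference dataset.

Three steps, in order: (1) mass matching of the sample's features to the
reference within a 0.01-Th tolerance, (2) migration-time alignment driven
by the matched internal standards (standards-seeded k-means clusters plus a
LOESS offset curve, iterated), (3) internal-standard LOESS intensity
normalization on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._smoothing import DEFAULT_SPAN, loess_predict
from .datatypes import FeatureKey, PeakList, ReferenceDataset
from .normalization import intensity_correction

log = logging.getLogger(__name__)

DEFAULT_MASS_TOL = 0.01
DEFAULT_MT_GATE = 60.0
DEFAULT_ITERATIONS = 5
MIN_STANDARDS_FOR_NORM = 10
NEW_SAMPLE_MT_WINDOW = (840.0, 3000.0)


@dataclass
class MatchResult:
    """Sample-to-reference feature assignment within the mass tolerance."""
    #: (sample feature id, reference feature id, delta m/z)
    pairs: list[tuple[str, str, float]]
    #: sample feature ids excluded from downstream analysis
    unmatched: list[str]
    #: subset of pairs whose reference feature is an internal standard
    standards_hit: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def pair_map(self) -> dict[str, str]:
        return {s: r for s, r, _ in self.pairs}


@dataclass
class AlignmentModel:
    """Diagnostics of the standards-driven migration-time alignment."""
    #: per cluster: (seed standard sample-feature id, cluster center s, offset s)
    clusters: list[tuple[str, float, float]]
    iterations: int
    fallback_constant: Optional[float] = None


def _constant_offset(sample_mt: np.ndarray, ref_mt: np.ndarray) -> float:
    return float(np.median(ref_mt - sample_mt))


def match_masses(pl: PeakList, ref: ReferenceDataset,
                 tol: float = DEFAULT_MASS_TOL,
                 mt_gate: Optional[float] = DEFAULT_MT_GATE) -> MatchResult:
    """Assign each sample feature to the nearest reference m/z within tol.

    ``mt_gate`` additionally restricts candidate reference features to
    |dMT| <= gate after a constant-offset coarse pre-alignment; pass None
    for mass-only matching. Equidistant m/z ties resolve to the smaller
    reference m/z. Unmatched features are excluded from further analysis
    but kept in the result for audit.
    """
    ref_ids = list(ref.matrix.feature_ids)
    ref_mz = ref.matrix.mz_array()
    ref_mt = ref.matrix.mt_array()
    order = np.lexsort((ref_mt, ref_mz))
    ref_ids = [ref_ids[i] for i in order]
    ref_mz, ref_mt = ref_mz[order], ref_mt[order]

    def assign(gate_offset: Optional[float]) -> tuple[list, list]:
        pairs, unmatched = [], []
        for fid, r in zip(pl.feature_ids, pl.table.itertuples()):
            lo = np.searchsorted(ref_mz, r.mz - tol, side="left")
            hi = np.searchsorted(ref_mz, r.mz + tol, side="right")
            cand = np.arange(lo, hi)
            if gate_offset is not None:
                cand = cand[np.abs(r.mt + gate_offset - ref_mt[cand])
                            <= mt_gate]
            if cand.size == 0:
                unmatched.append(fid)
                continue
            dmz = np.abs(ref_mz[cand] - r.mz)
            # ties on |dmz| resolve to the smaller reference m/z, which sorts
            # first; np.argmin keeps the first minimum
            best = cand[np.argmin(dmz)]
            pairs.append((fid, ref_ids[best], float(r.mz - ref_mz[best])))
        return pairs, unmatched

    rid_pos = {fid: i for i, fid in enumerate(ref_ids)}
    pairs, unmatched = assign(None)
    if mt_gate is not None and pairs:
        smt = pl.table.loc[[p[0] for p in pairs], "mt"].to_numpy()
        rmt = np.array([ref_mt[rid_pos[p[1]]] for p in pairs])
        offset = _constant_offset(smt, rmt)
        pairs, unmatched = assign(offset)
    if not pairs:
        raise ValueError(
            f"sample {pl.sample_id!r}: no features match the reference "
            f"within {tol} Th — sample incompatible with reference")
    stable = set(ref.stable)
    hits = [p for p in pairs if p[1] in stable]
    return MatchResult(pairs=pairs, unmatched=unmatched, standards_hit=hits)


def _lloyd_1d(points: np.ndarray, seeds: np.ndarray,
              max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """1-D k-means with fixed initial centroids; returns (labels, centers).

    An emptied cluster keeps its previous center so every seed standard
    retains a cluster.
    """
    centers = seeds.astype(float).copy()
    labels = np.zeros(points.size, dtype=int)
    for _ in range(max_iter):
        d = np.abs(points[:, None] - centers[None, :])
        new_labels = np.argmin(d, axis=1)
        new_centers = centers.copy()
        for k in range(centers.size):
            member = points[new_labels == k]
            if member.size:
                new_centers[k] = member.mean()
        if np.array_equal(new_labels, labels) and np.allclose(new_centers,
                                                              centers):
            break
        labels, centers = new_labels, new_centers
    return labels, centers


def align_migration_times(pl: PeakList,
                          standards: list[tuple[str, str, float]],
                          ref: ReferenceDataset,
                          iterations: int = DEFAULT_ITERATIONS,
                          span: float = DEFAULT_SPAN,
                          ) -> tuple[PeakList, AlignmentModel]:
    """Warp the sample's migration times onto the reference time base.

    Per iteration: k-means over all feature MTs with one cluster seeded at
    each matched standard's observed MT; each cluster's offset is reference
    MT minus observed MT of its seed standard; a LOESS curve of offset
    versus observed MT across the cluster seeds is applied to every
    feature. With fewer than two standards a constant-offset fallback is
    used (with a warning).
    """
    ref_mt_by_id = dict(zip(ref.matrix.feature_ids, ref.matrix.mt_array()))
    std_sample_ids = [s for s, _, _ in standards]
    std_ref_mt = np.array([ref_mt_by_id[r] for _, r, _ in standards])

    mt = pl.table["mt"].to_numpy().copy()
    idx = {fid: i for i, fid in enumerate(pl.feature_ids)}
    std_pos = np.array([idx[s] for s in std_sample_ids])

    if len(standards) < 2:
        if len(standards) == 0:
            raise ValueError("no matched standards; cannot align")
        log.warning("sample %s: only %d standard(s); constant-offset "
                    "alignment fallback", pl.sample_id, len(standards))
        off = float(std_ref_mt[0] - mt[std_pos[0]])
        model = AlignmentModel(clusters=[], iterations=0,
                               fallback_constant=off)
        return pl.with_mt(mt + off), model

    clusters_out: list[tuple[str, float, float]] = []
    for _ in range(iterations):
        seeds = mt[std_pos]
        _, centers = _lloyd_1d(mt, seeds)
        offsets = std_ref_mt - mt[std_pos]
        clusters_out = [(sid, float(c), float(o))
                        for sid, c, o in zip(std_sample_ids, centers, offsets)]
        correction = loess_predict(mt[std_pos], offsets, mt, span=span)
        mt = mt + correction
    return pl.with_mt(mt), AlignmentModel(clusters=clusters_out,
                                          iterations=iterations)


def normalize_intensities(pl: PeakList,
                          standards: list[tuple[str, str, float]],
                          ref: ReferenceDataset,
                          span: float = DEFAULT_SPAN,
                          min_standards: int = MIN_STANDARDS_FOR_NORM,
                          match: Optional[MatchResult] = None) -> PeakList:
    """LOESS intensity normalization against the internal standards.

    The normalization reference of a standard is its median log2 abundance
    across the reference runs; the fitted correction is subtracted in log2
    from every matched feature, looked up at the feature's own reference
    abundance (constant beyond the standards' range). Unmatched features
    pass through unchanged.
    """
    usable = [(s, r) for s, r, _ in standards
              if np.isfinite(pl.table.at[s, "intensity"])]
    if len(usable) < min_standards:
        raise ValueError(
            f"sample {pl.sample_id!r}: {len(usable)} usable internal "
            f"standards, at least {min_standards} required")
    ref_log2_all = ref.matrix.log2().median(axis=1, skipna=True)
    std_ref = np.array([ref_log2_all[r] for _, r in usable])
    std_obs = np.log2([pl.table.at[s, "intensity"] for s, _ in usable])

    pair_map = match.pair_map() if match is not None else {s: r for s, r, _
                                                           in standards}
    inten = pl.table["intensity"].to_numpy().copy()
    target_ids = [fid for fid in pl.feature_ids
                  if fid in pair_map and np.isfinite(pl.table.at[fid,
                                                                 "intensity"])]
    pos = pl.table.index.get_indexer(target_ids)
    eval_ref = np.array([ref_log2_all[pair_map[fid]] for fid in target_ids])
    corr = intensity_correction(std_ref, std_obs, eval_ref, span=span)
    inten[pos] = 2.0 ** (np.log2(inten[pos]) - corr)
    return pl.with_intensity(inten)


def process_sample(pl: PeakList, ref: ReferenceDataset,
                   tol: float = DEFAULT_MASS_TOL,
                   mt_gate: Optional[float] = DEFAULT_MT_GATE,
                   iterations: int = DEFAULT_ITERATIONS,
                   span: float = DEFAULT_SPAN,
                   mt_window: tuple[float, float] = NEW_SAMPLE_MT_WINDOW,
                   ) -> tuple[PeakList, MatchResult, dict]:
    """Full new-sample pipeline: window filter, match, align, normalize.

    Returns the normalized peak list (matched features only, original
    feature ids preserved), the match result, and a report dict with match
    counts and standard coverage.
    """
    from .reference import filter_mt_window

    pl = filter_mt_window(pl, *mt_window)
    match = match_masses(pl, ref, tol=tol, mt_gate=mt_gate)
    aligned, model = align_migration_times(pl, match.standards_hit, ref,
                                           iterations=iterations, span=span)
    normalized = normalize_intensities(aligned, match.standards_hit, ref,
                                       span=span, match=match)
    matched_ids = set(match.pair_map())
    out = normalized.subset([fid for fid in normalized.feature_ids
                             if fid in matched_ids])
    report = {
        "sample_id": pl.sample_id,
        "n_features": int(len(pl)),
        "n_matched": int(match.n_matched),
        "n_unmatched": int(len(match.unmatched)),
        "n_standards_hit": int(len(match.standards_hit)),
        "pct_standards_hit": (100.0 * len(match.standards_hit)
                              / max(len(ref.stable), 1)),
        "alignment_iterations": model.iterations,
    }
    return out, match, report


def process_cohort(pls: list[PeakList], ref: ReferenceDataset,
                   groups: Optional[pd.Series] = None, **kwargs):
    """Process every sample and stack the results on the reference's
    feature universe. Returns (FeatureMatrix, list of per-sample reports)."""
    processed, reports = [], []
    for pl in pls:
        out, match, report = process_sample(pl, ref, **kwargs)
        processed.append((out, match))
        reports.append(report)
    return matched_matrix(processed, ref, groups=groups), reports


def matched_matrix(pls_with_matches: list[tuple[PeakList, MatchResult]],
                   ref: ReferenceDataset,
                   groups: Optional[pd.Series] = None):
    """Stack normalized samples into a FeatureMatrix on the reference's
    feature universe (reference feature ids as rows)."""
    from .datatypes import FeatureMatrix

    cols = {}
    for pl, match in pls_with_matches:
        vals = pd.Series(np.nan, index=ref.matrix.feature_ids, dtype=float)
        for s, r in match.pair_map().items():
            v = pl.table.at[s, "intensity"] if s in pl.table.index else np.nan
            if np.isfinite(v):
                # two sample features may hit one reference feature; keep max
                prev = vals.at[r]
                vals.at[r] = v if not np.isfinite(prev) else max(prev, v)
        cols[pl.sample_id] = vals
    mat = pd.DataFrame(cols)
    return FeatureMatrix(mat, groups=groups)
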