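"""Selection of stable endogenous metabolite features (internal standards).

Two scoring strategies identify low-variability features across the
reference runs:

* *hyperline* (default): the Euclidean distance of each feature's abundance
  vector from the identity line x1 = x2 = ... = xn in sample space. In
  closed form d(v) = sqrt(sum_j (v_j - mean(v))^2) — translation along the
  line leaves it unchanged, so on the log2 scale a uniform dilution does
  not penalize a feature.
* *rlm*: residuals of robust (Huber) linear regressions of each sample's
  abundances against a per-feature median baseline; a feature's score is
  its worst absolute residual over samples.

The final set size is chosen by forward selection over the ascending
candidate list, minimizing M = MAD_j(median_i x_ij) of the normalized
matrix — the spread of the per-sample medians after normalizing with the
candidate prefix as standards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import FeatureMatrix
from .normalization import normalize_matrix

log = logging.getLogger(__name__)

DEFAULT_N_CANDIDATES = 1000
MIN_STABLE_SIZE = 10
#: candidates must be nearly complete across reference samples
CANDIDATE_MAX_MISSING = 0.10


@dataclass
class CandidateList:
    """Features ordered by ascending stability score."""
    entries: list[tuple[str, float]]
    method: str

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ValueError("candidate scores must be non-decreasing")

    @property
    def ids(self) -> list[str]:
        return [fid for fid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class StableSet:
    """Forward-selection result: the chosen standards and the search trace."""
    features: list[str]
    m_value: float
    trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.features)


def hyperline_distance(v: np.ndarray) -> float:
    """Euclidean distance from v to the identity line {t*(1,...,1)}."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if np.isnan(v).any():
        raise ValueError("vector contains missing values")
    return float(np.sqrt(np.sum((v - v.mean()) ** 2)))


def _candidate_pool(fm: FeatureMatrix, use_log2: bool = True) -> pd.DataFrame:
    """Nearly-complete features, residual gaps imputed with the feature median."""
    x = fm.log2() if use_log2 else fm.values
    miss = x.isna().mean(axis=1)
    pool = x.loc[miss <= CANDIDATE_MAX_MISSING]
    med = pool.median(axis=1, skipna=True)
    return pool.apply(lambda row: row.fillna(med[row.name]), axis=1)


def rlm_residual_scores(fm: FeatureMatrix,
                        baseline: pd.Series | None = None,
                        use_log2: bool = True,
                        aggregate: str = "max") -> pd.Series:
    """Per-feature stability score from robust regressions against a baseline.

    Each sample's abundances are regressed (Huber M-estimation, intercept
    included) on the baseline — by default the per-feature median across
    samples. A feature's score aggregates its absolute residuals over the
    sample models (``max`` by default, ``mean`` as the milder alternative);
    lower means more stable.
    """
    pool = _candidate_pool(fm, use_log2=use_log2)
    if baseline is None:
        baseline = pool.median(axis=1)
    else:
        baseline = baseline.loc[pool.index]
    if np.ptp(baseline.to_numpy()) == 0:
        raise ValueError("degenerate (constant) baseline")
    X = sm.add_constant(baseline.to_numpy())
    resid = np.empty((pool.shape[0], pool.shape[1]))
    for j, col in enumerate(pool.columns):
        y = pool[col].to_numpy()
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        resid[:, j] = np.abs(y - fit.fittedvalues)
    if aggregate == "max":
        scores = resid.max(axis=1)
    elif aggregate == "mean":
        scores = resid.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return pd.Series(scores, index=pool.index, name="rlm_score")


def hyperline_scores(fm: FeatureMatrix, use_log2: bool = True) -> pd.Series:
    pool = _candidate_pool(fm, use_log2=use_log2)
    d = pool.apply(lambda row: hyperline_distance(row.to_numpy()), axis=1)
    return d.rename("hyperline_distance")


def rank_candidates(fm: FeatureMatrix, method: str = "hyperline",
                    n_candidates: int = DEFAULT_N_CANDIDATES,
                    use_log2: bool = True) -> CandidateList:
    """Ascending-score candidate list; ties broken by feature id."""
    if method == "hyperline":
        scores = hyperline_scores(fm, use_log2=use_log2)
    elif method == "rlm":
        scores = rlm_residual_scores(fm, use_log2=use_log2)
    else:
        raise ValueError(f"unknown method {method!r}")
    if len(scores) < MIN_STABLE_SIZE:
        raise ValueError(
            f"candidate pool has {len(scores)} features; "
            f"at least {MIN_STABLE_SIZE} needed for forward selection")
    order = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    return CandidateList(entries=order[:n_candidates], method=method)


def variability_metric_M(fm_normalized: pd.DataFrame | FeatureMatrix) -> float:
    """M = MAD over samples of the per-sample median intensity.

    MAD is unscaled (no normal-consistency constant); missing values are
    ignored in the medians. An all-missing column is an error.
    """
    x = fm_normalized.values if isinstance(fm_normalized, FeatureMatrix) \
        else fm_normalized
    x = pd.DataFrame(x)
    if x.isna().all(axis=0).any():
        raise ValueError("a column is entirely missing")
    col_med = x.median(axis=0, skipna=True).to_numpy()
    return float(np.median(np.abs(col_med - np.median(col_med))))


def forward_select(fm: FeatureMatrix, cand: CandidateList,
                   start: int = MIN_STABLE_SIZE,
                   use_log2: bool = True, span: float = 0.75) -> StableSet:
    """Choose the stable-set size by minimizing M over candidate prefixes.

    For each prefix size k = start..len(cand), the whole matrix is
    normalized with the first k candidates as standards and M is computed;
    the smallest k attaining the minimal M wins. A normalization failure at
    some k records M = +inf for that size and the search continues.
    """
    if len(cand) < start:
        raise ValueError(f"candidate list shorter than start={start}")
    x = fm.log2() if use_log2 else fm.values
    ref = x.median(axis=1, skipna=True)
    trace: list[tuple[int, float]] = []
    for k in range(start, len(cand) + 1):
        ids = cand.ids[:k]
        try:
            normalized = normalize_matrix(x, ids, ref_log2=ref, span=span)
            m_k = variability_metric_M(normalized)
        except ValueError as exc:
            log.warning("forward selection: k=%d failed (%s)", k, exc)
            m_k = float("inf")
        trace.append((k, m_k))
    best_k, best_m = min(trace, key=lambda km: (km[1], km[0]))
    if not np.isfinite(best_m):
        raise ValueError("normalization failed at every candidate size")
    return StableSet(features=cand.ids[:best_k], m_value=best_m, trace=trace)


def select_stable_features(fm: FeatureMatrix, method: str = "hyperline",
                           n_candidates: int = DEFAULT_N_CANDIDATES,
                           start: int = MIN_STABLE_SIZE,
                           use_log2: bool = True) -> StableSet:
    """Rank candidates and run forward selection in one call."""
    cand = rank_candidates(fm, method=method, n_candidates=n_candidates,
                           use_log2=use_log2)
    return forward_select(fm, cand, start=start, use_log2=use_log2)
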