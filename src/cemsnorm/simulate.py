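"""Synthetic CE-MS cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
log-normal base abundances spanning about five orders of magnitude,
multiplicative per-sample dilution (additive on log2), a subset of
low-variability "stable" features spread over the whole intensity range,
group-differential features with a fixed fold change, smooth per-sample
migration-time warps, and zero-inflation of two kinds — technical
(left-censoring at a detection limit) and biological (a feature truly
absent in one group). Every stochastic quantity is drawn from one seeded
generator, so a config reproduces its cohort bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .datatypes import FeatureKey, FeatureMatrix, PeakList

TECHNICAL = "technical"
BIOLOGICAL = "biological"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the real study's shape: discovery cohort sizes 15
    (control) vs 34 (disease), log-normal base abundances (log2 ~
    N(18.5, 2.8), spanning ~5 orders of magnitude across 3 sd),
    10% stable features at ~5% biological CV, the rest on a continuum of
    log2 noise sds (0.45-1.2, i.e. roughly 35-130% CV), 30 two-fold
    differential features, ±40%-scale dilution (log2 sd 0.5), and
    left-censoring of the faintest 5% of intensities.
    """

    m: int = 200
    n_control: int = 15
    n_disease: int = 34
    fraction_stable: float = 0.10
    stable_cv: float = 0.05
    other_log2_sd: float = 0.45
    other_log2_sd_max: float = 1.20
    scale_log2_sd: float = 0.50
    #: systematic dilution offset (log2) of disease samples relative to
    #: control — impaired urine concentration shifts a whole group; 0 off
    group_scale_offset_log2: float = 0.0
    warp_family: str = "constant"  # constant | linear | spline | none
    warp_shift_sd: float = 10.0
    warp_slope_sd: float = 0.01
    warp_spline_magnitude: float = 15.0
    detection_quantile: float = 0.05
    #: width (log2 units) of the logistic detection curve around the limit;
    #: detection in MS is probabilistic in intensity, not a sharp cutoff
    detection_softness: float = 1.0
    absent_fraction: float = 0.0
    #: biological PMV model: within the affected group each sample lacks the
    #: metabolite with this probability, and carriers excrete it at an
    #: elevated level (bimodal presence/absence with compensatory abundance)
    absent_within_group: float = 0.7
    absent_present_boost_log2: float = 1.0
    n_differential: int = 30
    fold_change: float = 2.0
    #: log2 noise sd range of differential features (CV ~27-60%): a marker
    #: with a reproducible two-fold shift is by construction a feature of
    #: moderate biological variability
    differential_log2_sd: tuple[float, float] = (0.35, 0.70)
    #: sd (log2) of pervasive per-feature disease-vs-control offsets, the
    #: broad compositional shift real disease cohorts show on top of the
    #: planted fixed-fold differential features; 0 disables
    group_effect_log2_sd: float = 0.0
    base_log2_mean: float = 18.5
    base_log2_sd: float = 2.8
    mz_range: tuple[float, float] = (30.0, 650.0)
    mt_range: tuple[float, float] = (840.0, 3000.0)
    mz_jitter: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        for name in ("fraction_stable", "stable_cv", "detection_quantile",
                     "absent_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.m < 1 or self.n_control < 1 or self.n_disease < 1:
            raise ValueError("m and group sizes must be positive")
        n_stable = int(round(self.fraction_stable * self.m))
        n_absent = int(round(self.absent_fraction * self.m))
        if n_stable + self.n_differential + n_absent > self.m:
            raise ValueError(
                "stable, differential and absent features exceed m: "
                "a feature cannot carry two contradictory roles")
        if self.warp_family not in ("constant", "linear", "spline", "none"):
            raise ValueError(f"unknown warp family {self.warp_family!r}")
        if self.other_log2_sd_max < self.other_log2_sd:
            raise ValueError("other_log2_sd_max must be >= other_log2_sd")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")

    @property
    def stable_log2_sd(self) -> float:
        # CV of a log-normal with log2-sd s is ~ s*ln2 for small s
        return math.log2(1.0 + self.stable_cv)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated cohort."""

    scale_log2: pd.Series                      # per-sample dilution, log2
    warp: dict[str, Callable[[np.ndarray], np.ndarray]]  # per-sample MT warp
    true_mt: pd.Series                         # per-feature unwarped MT
    stable_ids: list[str]
    differential_ids: list[str]
    absent: dict[str, list[str]]               # group label -> feature ids
    missing_mechanism: pd.DataFrame            # "", "technical", "biological"
    base_log2: pd.Series
    group_effect_log2: pd.Series | None = None  # pervasive disease offsets


@dataclass
class SimulatedCohort:
    peak_lists: list[PeakList]
    matrix: FeatureMatrix
    truth: SyntheticTruth
    config: SimulationConfig = field(repr=False, default=None)


def _make_warp(cfg: SimulationConfig, rng: np.random.Generator
               ) -> Callable[[np.ndarray], np.ndarray]:
    lo, hi = cfg.mt_range
    if cfg.warp_family == "none":
        return lambda mt: mt
    if cfg.warp_family == "constant":
        shift = rng.normal(0.0, cfg.warp_shift_sd)
        return lambda mt, s=shift: mt + s
    if cfg.warp_family == "linear":
        slope = rng.normal(1.0, cfg.warp_slope_sd)
        icpt = rng.normal(0.0, cfg.warp_shift_sd)
        mid = 0.5 * (lo + hi)
        return lambda mt, a=icpt, b=slope, c=mid: c + b * (mt - c) + a
    # smooth spline-like warp: low-frequency sinusoid
    amp = rng.uniform(0.3, 1.0) * cfg.warp_spline_magnitude
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    span = hi - lo
    return lambda mt, a=amp, f=freq, p=phase: (
        mt + a * np.sin(2 * np.pi * f * (mt - lo) / span + p))


def generate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort: per-sample peak lists, the clean feature matrix
    (unwarped coordinates, NaN where missing), and the planted truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # feature universe with unique rendered ids
    ids: list[str] = []
    mz = np.empty(cfg.m)
    mt = np.empty(cfg.m)
    seen: set[str] = set()
    i = 0
    while i < cfg.m:
        a = rng.uniform(*cfg.mz_range)
        t = rng.uniform(*cfg.mt_range)
        fid = FeatureKey(a, t).id
        if fid in seen:
            continue
        seen.add(fid)
        ids.append(fid)
        mz[i], mt[i] = a, t
        i += 1

    # roles: stable features spread over the abundance range, then
    # differential and biologically-absent features among the rest
    n_stable = int(round(cfg.fraction_stable * cfg.m))
    # log-normal abundances: normal on log2, ~5 orders of magnitude at 3 sd
    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=cfg.m)
    order_by_abundance = np.argsort(base)
    # standards span the abundance range but sit above the censoring zone:
    # a feature that dips below the detection limit cannot serve as one
    floor = int(np.ceil(max(0.15, 2 * cfg.detection_quantile) * cfg.m))
    floor = min(floor, cfg.m - 1)
    stable_pos = (order_by_abundance[
        np.linspace(floor, cfg.m - 1, n_stable).astype(int)]
        if n_stable else np.array([], dtype=int))
    rest = np.setdiff1d(np.arange(cfg.m), stable_pos)
    rest = rng.permutation(rest)
    diff_pos = rest[:cfg.n_differential]
    n_absent = int(round(cfg.absent_fraction * cfg.m))
    absent_pos = rest[cfg.n_differential:cfg.n_differential + n_absent]

    samples = ([f"control_{i+1:02d}" for i in range(cfg.n_control)]
               + [f"disease_{i+1:02d}" for i in range(cfg.n_disease)])
    groups = pd.Series(["control"] * cfg.n_control
                       + ["disease"] * cfg.n_disease, index=samples)

    scale = rng.normal(0.0, cfg.scale_log2_sd, size=len(samples))
    scale[cfg.n_control:] += cfg.group_scale_offset_log2
    # non-stable features carry a continuum of biological variabilities,
    # as real metabolite CVs do
    sd_vec = rng.uniform(cfg.other_log2_sd, cfg.other_log2_sd_max,
                         size=cfg.m)
    sd_vec[stable_pos] = cfg.stable_log2_sd
    if len(diff_pos):
        lo, hi = cfg.differential_log2_sd
        lo = min(lo, cfg.other_log2_sd_max)
        hi = min(hi, cfg.other_log2_sd_max)
        sd_vec[diff_pos] = rng.uniform(lo, hi, size=len(diff_pos))

    log2x = (base[:, None] + scale[None, :]
             + rng.normal(0.0, 1.0, size=(cfg.m, len(samples))) * sd_vec[:, None])
    is_disease = (groups == "disease").to_numpy()
    log2x[np.ix_(diff_pos, np.where(is_disease)[0])] += math.log2(cfg.fold_change)
    group_effect = np.zeros(cfg.m)
    if cfg.group_effect_log2_sd > 0:
        group_effect = rng.normal(0.0, cfg.group_effect_log2_sd, size=cfg.m)
        group_effect[stable_pos] = 0.0  # stable features stay stable
        log2x[:, is_disease] += group_effect[:, None]

    x = 2.0 ** log2x
    mech = np.full((cfg.m, len(samples)), "", dtype=object)

    # biological absence: in the affected group the metabolite is missing
    # from a random subset of samples and elevated in the carriers
    absent: dict[str, list[str]] = {"control": [], "disease": []}
    for pos in absent_pos:
        g = "disease" if rng.random() < 0.5 else "control"
        cols = np.where(is_disease if g == "disease" else ~is_disease)[0]
        gone = cols[rng.random(cols.size) < cfg.absent_within_group]
        kept = np.setdiff1d(cols, gone)
        x[pos, gone] = np.nan
        mech[pos, gone] = BIOLOGICAL
        x[pos, kept] *= 2.0 ** cfg.absent_present_boost_log2
        absent[g].append(ids[pos])

    # technical censoring: probabilistic left-censoring around the
    # detection-limit quantile (logistic in log2 intensity)
    if cfg.detection_quantile > 0:
        finite = np.log2(x[np.isfinite(x)])
        limit = np.quantile(finite, cfg.detection_quantile)
        with np.errstate(invalid="ignore"):
            z = (limit - np.log2(np.where(np.isfinite(x), x, 1.0))) \
                / max(cfg.detection_softness, 1e-9)
        p_miss = 1.0 / (1.0 + np.exp(-z))
        cens = np.isfinite(x) & (rng.random(x.shape) < p_miss)
        x[cens] = np.nan
        mech[cens] = TECHNICAL

    matrix = FeatureMatrix(pd.DataFrame(x, index=ids, columns=samples),
                           groups=groups)

    warps: dict[str, Callable] = {}
    peak_lists = []
    for j, sid in enumerate(samples):
        w = _make_warp(cfg, rng)
        warps[sid] = w
        obs = np.isfinite(x[:, j])
        tab = pd.DataFrame({
            "mz": mz[obs] + rng.uniform(-cfg.mz_jitter, cfg.mz_jitter,
                                        size=int(obs.sum())),
            "mt": w(mt[obs]),
            "intensity": x[obs, j],
        })
        pl = PeakList(sid, tab)
        # keep the planted feature identity as the index so ground-truth
        # cross-referencing survives warping and jitter
        pl.table.index = pd.Index([ids[k] for k in np.where(obs)[0]],
                                  name="feature_id")
        peak_lists.append(pl)

    truth = SyntheticTruth(
        scale_log2=pd.Series(scale, index=samples),
        warp=warps,
        true_mt=pd.Series(mt, index=ids),
        stable_ids=[ids[p] for p in stable_pos],
        differential_ids=[ids[p] for p in diff_pos],
        absent=absent,
        missing_mechanism=pd.DataFrame(mech, index=ids, columns=samples),
        base_log2=pd.Series(base, index=ids),
        group_effect_log2=pd.Series(group_effect, index=ids),
    )
    return SimulatedCohort(peak_lists=peak_lists, matrix=matrix, truth=truth,
                           config=cfg)


def set_recovery(predicted, truth_set) -> dict:
    """Precision/recall of a recovered feature set against the planted one.

    Precision is reported as None (missing) for an empty prediction.
    """
    pred, true = set(predicted), set(truth_set)
    tp = len(pred & true)
    return {
        "precision": (tp / len(pred)) if pred else None,
        "recall": (tp / len(true)) if true else None,
        "n_predicted": len(pred),
        "n_true": len(true),
    }


def warp_rmse(truth: SyntheticTruth, pl: PeakList,
              feature_ids: Optional[list[str]] = None) -> float:
    """RMSE of a (possibly aligned) peak list's MTs against the true,
    unwarped MTs, over the requested features (default: all shared)."""
    if feature_ids is None:
        feature_ids = [f for f in pl.feature_ids if f in truth.true_mt.index]
    obs = pl.table.loc[feature_ids, "mt"].to_numpy()
    true = truth.true_mt.loc[feature_ids].to_numpy()
    return float(np.sqrt(np.mean((obs - true) ** 2)))


def scale_factor_error(truth: SyntheticTruth,
                       estimated_log2: pd.Series) -> pd.Series:
    """Relative error of estimated multiplicative per-sample scale factors."""
    est = 2.0 ** estimated_log2
    true = 2.0 ** truth.scale_log2.reindex(estimated_log2.index)
    return (est / true - 1.0).abs()


def truth_metrics(truth: SyntheticTruth,
                  stable_predicted=None,
                  differential_predicted=None,
                  aligned_peak_lists: Optional[list[PeakList]] = None,
                  estimated_scale_log2: Optional[pd.Series] = None) -> dict:
    """Recovery report for whichever pipeline outputs are supplied."""
    report: dict = {}
    if stable_predicted is not None:
        report["stable"] = set_recovery(stable_predicted, truth.stable_ids)
    if differential_predicted is not None:
        report["differential"] = set_recovery(differential_predicted,
                                              truth.differential_ids)
    if aligned_peak_lists is not None:
        report["warp_rmse"] = {pl.sample_id: warp_rmse(truth, pl)
                               for pl in aligned_peak_lists}
    if estimated_scale_log2 is not None:
        err = scale_factor_error(truth, estimated_scale_log2)
        report["scale_factor"] = {"median_rel_error": float(err.median()),
                                  "max_rel_error": float(err.max())}
    return report
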