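"""Quality-control statistics and point-mass-at-zero (PMV) analysis.

CE-MS intensity matrices are bimodal: a continuous component plus a point
mass at zero (missing values, since zero intensities are treated as
missing). PMVs can be technical (below the detection limit) or biological
(the metabolite is truly absent). In a two-group comparison a feature is
*consonant* when the group with the higher PMV proportion has the smaller
mean in the continuous part — the signature of detection-limit censoring —
and *dissonant* when that group has the higher continuous mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix

CONSONANT = "consonant"
DISSONANT = "dissonant"
NO_POINT_MASS = "no_point_mass"


@dataclass
class PmvClassification:
    """Per-feature PMV proportions, continuous-part means, and labels."""
    table: pd.DataFrame  # columns: pmv_<g>, mean_<g> per group, label
    group_labels: tuple[str, str]

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def feature_cv(fm: FeatureMatrix) -> pd.Series:
    """Coefficient of variation per feature, in percent.

    Sample standard deviation over mean of the non-missing raw intensities;
    undefined (NaN) with fewer than two observed values.
    """
    x = fm.values
    n_obs = x.notna().sum(axis=1)
    mean = x.mean(axis=1, skipna=True)
    sd = x.std(axis=1, ddof=1, skipna=True)
    cv = sd / mean * 100.0
    cv[n_obs < 2] = np.nan
    return cv.rename("cv_percent")


def detection_rate(fm: FeatureMatrix, ref_size: int) -> pd.DataFrame:
    """Per-run detected feature count and fraction of the reference."""
    detected = fm.values.notna().sum(axis=0)
    if (detected > ref_size).any():
        raise ValueError("ref_size smaller than a run's detected count")
    return pd.DataFrame({"detected": detected,
                         "fraction": detected / ref_size})


def classify_pmv(fm: FeatureMatrix) -> PmvClassification:
    """Label every feature consonant / dissonant / no_point_mass.

    Requires a two-group matrix with >=2 samples per group. Ties in PMV
    proportion (both nonzero) classify consonant: the dissonant label
    requires the higher-PMV group to also have the strictly higher
    continuous mean, which a tie cannot establish. A group with no observed
    values has an undefined continuous mean and is treated as the smaller
    mean (absent and undetected), hence consonant.
    """
    cols = fm.group_columns()
    if len(cols) != 2:
        raise ValueError(f"need exactly two groups, got {sorted(cols)}")
    (ga, ca), (gb, cb) = sorted(cols.items())
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("each group needs >=2 samples")
    xa, xb = fm.values[ca], fm.values[cb]
    pmv_a = xa.isna().mean(axis=1)
    pmv_b = xb.isna().mean(axis=1)
    mean_a = xa.mean(axis=1, skipna=True)
    mean_b = xb.mean(axis=1, skipna=True)

    labels = []
    for fid in fm.feature_ids:
        pa, pb = pmv_a[fid], pmv_b[fid]
        if pa == 0 and pb == 0:
            labels.append(NO_POINT_MASS)
            continue
        if pa > pb:
            hi_mean, lo_mean = mean_a[fid], mean_b[fid]
        elif pb > pa:
            hi_mean, lo_mean = mean_b[fid], mean_a[fid]
        else:  # tie, both nonzero
            labels.append(CONSONANT)
            continue
        if np.isnan(hi_mean):
            labels.append(CONSONANT)
        elif np.isnan(lo_mean) or hi_mean <= lo_mean:
            labels.append(CONSONANT)
        else:
            labels.append(DISSONANT)

    table = pd.DataFrame({
        f"pmv_{ga}": pmv_a, f"pmv_{gb}": pmv_b,
        f"mean_{ga}": mean_a, f"mean_{gb}": mean_b,
        "label": labels,
    }, index=fm.feature_ids)
    return PmvClassification(table=table, group_labels=(ga, gb))


def pmv_summary(cls: PmvClassification) -> pd.DataFrame:
    """Counts and integer-rounded percentages per PMV label."""
    counts = cls.labels.value_counts()
    total = int(counts.sum())
    rows = []
    for label in (CONSONANT, DISSONANT, NO_POINT_MASS):
        c = int(counts.get(label, 0))
        rows.append({"label": label, "count": c,
                     "percent": int(round(100.0 * c / total))})
    return pd.DataFrame(rows).set_index("label")
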