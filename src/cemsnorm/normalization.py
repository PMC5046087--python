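"""Internal-standard-based intensity normalization core.

Normalization works on the log2 scale, where multiplicative dilution
becomes an additive offset. For one sample, a LOESS curve is fit through
the points (reference log2 abundance of each standard, observed log2
abundance of that standard); the correction c(x) = fitted(x) - x is then
subtracted from every feature's log2 intensity, looked up at the feature's
reference abundance. Outside the standards' abundance range the correction
is held constant at the boundary value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._smoothing import DEFAULT_SPAN, loess_predict


def intensity_correction(standard_ref_log2: np.ndarray,
                         standard_obs_log2: np.ndarray,
                         eval_ref_log2: np.ndarray,
                         span: float = DEFAULT_SPAN) -> np.ndarray:
    """Correction (in log2 units) to subtract from observed intensities.

    Parameters are the standards' reference abundances, their observed
    abundances in the sample, and the reference abundances at which the
    correction is evaluated (one per feature to correct).
    """
    lo = np.min(standard_ref_log2)
    hi = np.max(standard_ref_log2)
    # hold the *correction* constant beyond the standards' range
    xc = np.clip(np.asarray(eval_ref_log2, dtype=float), lo, hi)
    fitted = loess_predict(standard_ref_log2, standard_obs_log2, xc,
                           span=span)
    return fitted - xc


def normalize_matrix(log2_matrix: pd.DataFrame, standard_ids: list[str],
                     ref_log2: pd.Series | None = None,
                     span: float = DEFAULT_SPAN) -> pd.DataFrame:
    """Normalize every column of a log2 intensity matrix.

    ``ref_log2`` is the normalization reference per feature: by default the
    median log2 abundance across the matrix's own columns. Missing entries
    stay missing; standards missing in a given column are dropped from that
    column's fit.
    """
    if ref_log2 is None:
        ref_log2 = log2_matrix.median(axis=1, skipna=True)
    std_ref = ref_log2.loc[standard_ids]
    out = {}
    for col in log2_matrix.columns:
        y = log2_matrix.loc[standard_ids, col]
        ok = y.notna() & std_ref.notna()
        if ok.sum() < 2:
            raise ValueError(
                f"sample {col!r}: fewer than two usable standards")
        corr = intensity_correction(std_ref[ok].to_numpy(),
                                    y[ok].to_numpy(),
                                    ref_log2.to_numpy(), span=span)
        out[col] = log2_matrix[col].to_numpy() - corr
    return pd.DataFrame(out, index=log2_matrix.index)
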