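"""LOESS smoothing helper shared by migration-time alignment and
intensity normalization.

statsmodels' lowess returns fitted values only at the training abscissae;
``loess_predict`` interpolates linearly between them and holds the boundary
value constant outside the training range (LOESS extrapolation is
ill-defined). With fewer than four training points a plain linear
least-squares fit is used instead — a local regression is meaningless there.
"""

from __future__ import annotations

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_SPAN = 0.75


def loess_predict(x_train: np.ndarray, y_train: np.ndarray,
                  x_eval: np.ndarray, span: float = DEFAULT_SPAN) -> np.ndarray:
    """Fit y ~ x by LOESS (degree-1 local fits) and evaluate at ``x_eval``.

    Outside [min(x_train), max(x_train)] the prediction is held constant at
    the boundary fitted value.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    if x_train.size != y_train.size or x_train.size == 0:
        raise ValueError("x_train and y_train must be equal-length, non-empty")
    if x_train.size == 1:
        return np.full_like(x_eval, y_train[0])
    if np.ptp(x_train) == 0:
        return np.full_like(x_eval, float(np.mean(y_train)))
    if x_train.size < 4:
        slope, icpt = np.polyfit(x_train, y_train, 1)
        lo, hi = x_train.min(), x_train.max()
        return slope * np.clip(x_eval, lo, hi) + icpt
    # delta skips local fits at near-duplicate abscissae (linear interpolation
    # in between) — the standard lowess speedup, negligible at this scale
    fitted = lowess(y_train, x_train, frac=span, it=1,
                    delta=0.005 * np.ptp(x_train), return_sorted=True)
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate abscissae so np.interp sees strictly increasing x
    xs_u, idx = np.unique(xs, return_index=True)
    ys_u = np.array([ys[xs == v].mean() for v in xs_u]) if len(xs_u) < len(xs) \
        else ys[idx]
    return np.interp(x_eval, xs_u, ys_u)  # np.interp clamps at the edges
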