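"""Internal numerical helpers shared by metrics and volmer modules."""

from __future__ import annotations

import numpy as np

__all__ = ["local_quadratic_slope", "shoelace_area"]


def local_quadratic_slope(
    x: np.ndarray, y: np.ndarray, window: int
) -> np.ndarray:
    """dy/dx at every sample via centered local least-squares quadratics.

    At each point a quadratic is fitted by least squares to the
    ``window`` points centered there (windows shrink one-sidedly at the
    ends) in coordinates relative to the evaluation point, so the slope
    is the linear coefficient. Handles non-uniform ``x`` spacing exactly;
    deterministic, no stochastic smoothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 5")
    if n < window:
        raise ValueError(f"need at least {window} points, got {n}")
    half = window // 2
    out = np.empty(n)

    # Interior: full windows, vectorized normal equations. Each window is
    # rescaled by its span for conditioning.
    xw = np.lib.stride_tricks.sliding_window_view(x, window)  # (m, w)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    centers = x[half: n - half][:, None]
    dx = xw - centers
    scale = np.max(np.abs(dx), axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    u = dx / scale
    # Moments of the design [1, u, u^2].
    s0 = np.full(len(u), float(window))
    s1 = u.sum(axis=1)
    s2 = (u**2).sum(axis=1)
    s3 = (u**3).sum(axis=1)
    s4 = (u**4).sum(axis=1)
    b0 = yw.sum(axis=1)
    b1 = (u * yw).sum(axis=1)
    b2 = (u**2 * yw).sum(axis=1)
    mats = np.empty((len(u), 3, 3))
    mats[:, 0, 0] = s0
    mats[:, 0, 1] = mats[:, 1, 0] = s1
    mats[:, 0, 2] = mats[:, 1, 1] = mats[:, 2, 0] = s2
    mats[:, 1, 2] = mats[:, 2, 1] = s3
    mats[:, 2, 2] = s4
    rhs = np.stack([b0, b1, b2], axis=1)[..., None]
    try:
        beta = np.linalg.solve(mats, rhs)[:, :, 0]
    except np.linalg.LinAlgError:
        beta = np.stack(
            [
                np.linalg.lstsq(m, r[:, 0], rcond=None)[0]
                for m, r in zip(mats, rhs)
            ]
        )
    out[half: n - half] = beta[:, 1] / scale[:, 0]

    # Edges: shrinking one-sided windows (at least 3 points for a quadratic).
    for i in list(range(half)) + list(range(n - half, n)):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        dxe = x[lo:hi] - x[i]
        se = np.max(np.abs(dxe)) or 1.0
        ue = dxe / se
        design = np.column_stack([np.ones_like(ue), ue, ue**2])
        coef, *_ = np.linalg.lstsq(design, y[lo:hi], rcond=None)
        out[i] = coef[1] / se
    return out


def shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Gauss (shoelace) signed area of the closed polygon (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed))
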