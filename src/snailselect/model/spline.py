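"""Knot selection and the truncated-power spline basis.

The number of knots follows Ruppert's rule K = min(floor(I/4), 35) for I
marked individuals; knots sit at the k/(K+1) empirical quantiles of the
shell-colour values (linear-interpolation quantiles, the type-7 convention).
"""

from __future__ import annotations

import numpy as np

MAX_KNOTS = 35


def knot_count(I: int) -> int:
    """Number of spline knots for a dataset of ``I`` individuals.

    K = min(floor(I/4), 35); fewer than 8 individuals would give K < 2,
    which cannot support a spline, and raises.
    """
    I = int(I)
    if I < 8:
        raise ValueError(f"too few individuals (I={I}): knot count would be < 2")
    return min(I // 4, MAX_KNOTS)


def knot_positions(colours, K: int) -> np.ndarray:
    """Knots at the k/(K+1) quantiles of the colour values, k = 1..K."""
    colours = np.asarray(colours, dtype=float)
    if colours.size <= K:
        raise ValueError(f"need more than K={K} colour values")
    probs = np.arange(1, K + 1) / (K + 1)
    knots = np.quantile(colours, probs)  # linear interpolation (type 7)
    if np.any(np.diff(knots) <= 0):
        dupes = knots[np.concatenate(([False], np.diff(knots) <= 0))]
        raise ValueError(
            f"duplicate knots at {np.unique(dupes)}: too few distinct colour values"
        )
    return knots


def spline_basis(col, knots, P: int = 3) -> np.ndarray:
    """Truncated-power basis (col, ..., col^P, (col-kappa_1)_+^P, ...).

    Returns shape (P + K,) for scalar input, else (n, P + K).
    """
    knots = np.asarray(knots, dtype=float)
    if knots.size > 1 and np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    scalar = np.isscalar(col) or np.ndim(col) == 0
    col = np.atleast_1d(np.asarray(col, dtype=float))
    powers = np.column_stack([col**p for p in range(1, P + 1)])
    hinge = np.clip(col[:, None] - knots[None, :], 0.0, None) ** P
    out = np.hstack([powers, hinge])
    return out[0] if scalar else out
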