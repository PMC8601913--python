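"""Shell-colour quantification from RGB pixel samples.

Shell brightness is measured as the luminance ``Y = 0.299 R + 0.587 G +
0.114 B`` of pixels sampled from a photograph of the shell, corrected by the
luminance ``Y'`` of a grey card photographed alongside (the ratio ``Y/Y'``
removes lighting differences between shots), and finally z-standardised over
the analysis set.  Higher ratios mean brighter shells.

Image decoding is out of scope: callers pass pixel arrays (any ``(..., 3)``
uint array) or per-individual channel means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: ITU-R BT.601 luma coefficients for (R, G, B).
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PixelSample:
    """A reproducible random sample of pixels from a cropped shell image.

    Attributes
    ----------
    pixels : ndarray of shape (n, 3)
        Sampled (R, G, B) triples, each channel in [0, 255].
    n : int
        Number of sampled pixels.
    seed : int
        RNG seed used to draw the sample; resampling with the same seed
        from the same region reproduces the sample exactly.
    """

    pixels: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[1] != 3:
            raise ValueError("pixels must have shape (n, 3)")
        if px.shape[0] != self.n:
            raise ValueError(f"n={self.n} does not match {px.shape[0]} pixels")
        if px.min(initial=0) < 0 or px.max(initial=0) > 255:
            raise ValueError("pixel channels must lie in [0, 255]")

    @property
    def mean_rgb(self) -> np.ndarray:
        """Channel means of the sample, shape (3,)."""
        return np.asarray(self.pixels, dtype=float).mean(axis=0)


def luminance(rgb_mean: Sequence[float]) -> float:
    """Luminance ``Y = 0.299 R + 0.587 G + 0.114 B`` of an RGB triple.

    Parameters
    ----------
    rgb_mean : sequence of 3 floats
        Mean channel values, each in [0, 255].

    Returns
    -------
    float
        Luminance on the same 0-255 scale (the coefficients sum to 1).
    """
    rgb = np.asarray(rgb_mean, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("rgb_mean must be a length-3 sequence")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("RGB channels must lie in [0, 255]")
    return float(LUMA_WEIGHTS @ rgb)


def sample_pixels(region: np.ndarray, n: int = 1000, *, seed: int) -> PixelSample:
    """Draw ``n`` pixels uniformly with replacement from a pixel region.

    Parameters
    ----------
    region : ndarray of shape (h, w, 3) or (m, 3)
        Cropped image region (or flat pixel list) with channels in [0, 255].
    n : int
        Number of pixels to draw (default 1000).
    seed : int
        Mandatory RNG seed; identical seeds give identical samples.
    """
    region = np.asarray(region)
    if region.ndim == 3 and region.shape[-1] == 3:
        flat = region.reshape(-1, 3)
    elif region.ndim == 2 and region.shape[-1] == 3:
        flat = region
    else:
        raise ValueError("region must have shape (h, w, 3) or (m, 3)")
    if flat.shape[0] == 0:
        raise ValueError("region is empty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, flat.shape[0], size=n)
    return PixelSample(pixels=flat[idx], n=n, seed=seed)


def grey_correct(y_shell: float, y_grey: float) -> float:
    """Grey-card correction: the ratio ``Y / Y'`` of shell to grey luminance.

    Raises
    ------
    ValueError
        If the grey-card luminance is not strictly positive.
    """
    if y_grey <= 0:
        raise ValueError("grey-card luminance must be > 0")
    return float(y_shell) / float(y_grey)


def standardize(ratios: Sequence[float]) -> np.ndarray:
    """z-score a vector of corrected colour ratios (sample SD, ddof=1).

    The standardised colour has mean 0 and sample standard deviation 1 over
    the analysis set, and preserves rank order.  Standardisation is applied
    over the full dataset being fitted (one site at a time).
    """
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: colour values are all identical")
    return (x - x.mean()) / sd


def colour_summary(sample_a: Sequence[float], sample_b: Sequence[float]) -> dict:
    """Compare two colour distributions (e.g. mainland vs. island).

    Returns medians and variances per sample, a two-sided Wilcoxon rank-sum
    p value (exact for group sizes <= 20, tie-corrected normal approximation
    with continuity correction otherwise) and a two-sided variance-ratio
    F-test p value.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")

    method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
    wil = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)

    f_stat = a.var(ddof=1) / b.var(ddof=1)
    cdf = stats.f.cdf(f_stat, a.size - 1, b.size - 1)
    f_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))

    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "var_a": float(a.var(ddof=1)),
        "var_b": float(b.var(ddof=1)),
        "wilcoxon_p": float(wil.pvalue),
        "f_statistic": float(f_stat),
        "vartest_p": f_p,
    }


def quantify_table(df: pd.DataFrame) -> pd.DataFrame:
    """Run the colour pipeline over a per-individual table.

    Expects columns ``R_mean, G_mean, B_mean, Y_grey`` (one row per
    individual); returns a copy with ``Y_shell``, ``ratio`` and the
    z-standardised ``col`` appended.
    """
    required = {"R_mean", "G_mean", "B_mean", "Y_grey"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    rgb = out[["R_mean", "G_mean", "B_mean"]].to_numpy(dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("RGB channels must lie in [0, 255]")
    y = rgb @ LUMA_WEIGHTS
    y_grey = out["Y_grey"].to_numpy(dtype=float)
    if np.any(y_grey <= 0):
        raise ValueError("grey-card luminance must be > 0")
    out["Y_shell"] = y
    out["ratio"] = y / y_grey
    out["col"] = standardize(out["ratio"].to_numpy())
    return out
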