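"""Slice quality metrics: LoG sharpness, Fourier Ring Correlation, detection.

Sharpness of a slice is the standard deviation of its Laplacian-of-Gaussian
response; out-of-focus slices have markedly lower values.  Artifactual
slices are flagged by a robust rule on the per-slice sharpness series
(below ``median - k * MAD`` by default).

The Fourier Ring Correlation of two images is the normalized cross-spectral
correlation computed over concentric rings of spatial frequency r:

    FRC(r) = Re( sum_{r_i in r} F1(r_i) * conj(F2(r_i)) )
             / sqrt( sum |F1(r_i)|^2 * sum |F2(r_i)|^2 )

The *global* FRC score is the unweighted mean of FRC(r) over all rings and
is the acceptance statistic used to decide whether a restored slice is as
coherent with its neighborhood as an untouched one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage

from .core_io import ImageStack

__all__ = [
    "FRCCurve",
    "SliceQualityReport",
    "sharpness",
    "frc",
    "detect_artifactual_slices",
    "frc_validation",
]

logger = logging.getLogger(__name__)

DEFAULT_LOG_SIGMA = 2.0
DEFAULT_PLANE_RANGE = 3


@dataclass
class FRCCurve:
    """Per-ring Fourier correlation plus the global (mean) score.

    Attributes
    ----------
    ring_radii
        Center spatial frequency of each ring, in cycles/pixel.
    values
        FRC(r) per ring; each lies in [-1, 1] by Cauchy-Schwarz.
    ring_counts
        Number of Fourier samples binned into each ring.
    global_score
        Unweighted mean of `values`.
    """

    ring_radii: np.ndarray
    values: np.ndarray
    ring_counts: np.ndarray
    global_score: float

    def weighted_score(self) -> float:
        """Alternative global score weighting rings by their sample count."""
        w = self.ring_counts.astype(float)
        return float(np.sum(self.values * w) / np.sum(w))


@dataclass
class SliceQualityReport:
    """Per-slice sharpness values and the slices flagged as artifactual."""

    sharpness: np.ndarray
    flagged: List[int]
    threshold_rule: dict = field(default_factory=dict)

    @property
    def n_z(self) -> int:
        return len(self.sharpness)


def sharpness(image: np.ndarray, log_sigma: float = DEFAULT_LOG_SIGMA) -> float:
    """Standard deviation of the Laplacian-of-Gaussian filtered slice.

    Mirror boundary handling avoids spurious edge response dominating the
    statistic.  Exactly 0 for constant input and invariant to an additive
    intensity offset (the LoG response of a constant is itself constant).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError(f"image must be 2-D and >= 3x3, got shape {img.shape}")
    if log_sigma <= 0:
        raise ValueError("log_sigma must be > 0")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    filtered = ndimage.gaussian_laplace(img, log_sigma, mode="mirror")
    return float(filtered.std())


def _ring_bins(shape: Tuple[int, int], ring_width: Optional[float]):
    """Ring index per Fourier sample; DC and radii beyond Nyquist get -1.

    Frequencies are normalized per axis to cycles/pixel so Nyquist sits at
    0.5 on both axes regardless of aspect ratio.  Default ring width is one
    Fourier pixel of the larger axis.
    """
    n_y, n_x = shape
    if ring_width is None:
        ring_width = 1.0 / max(n_y, n_x)
    if ring_width <= 0:
        raise ValueError("ring_width must be > 0")
    fy = np.fft.fftfreq(n_y)[:, None]
    fx = np.fft.fftfreq(n_x)[None, :]
    r = np.hypot(fy, fx)
    idx = np.ceil(r / ring_width).astype(int) - 1  # ring k covers (k*w, (k+1)*w]
    idx[r == 0] = -1          # DC excluded: it only encodes mean intensity
    idx[r > 0.5] = -1         # corners beyond Nyquist excluded
    n_rings = int(np.ceil(0.5 / ring_width))
    idx[idx >= n_rings] = n_rings - 1
    return idx, n_rings, ring_width


def frc(
    image_a: np.ndarray,
    image_b: np.ndarray,
    ring_width: Optional[float] = None,
) -> FRCCurve:
    """Fourier Ring Correlation between two equally shaped images.

    Rings partition normalized spatial frequency from just above 0 (DC is
    excluded) to Nyquist (0.5 cycles/pixel).  A ring with zero spectral
    power in either image contributes a value of 0 (logged at debug level).
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or min(a.shape) < 8:
        raise ValueError(f"images must be 2-D and >= 8x8, got {a.shape}")

    idx, n_rings, rw = _ring_bins(a.shape, ring_width)
    f1 = np.fft.fft2(a)
    f2 = np.fft.fft2(b)

    flat = idx.ravel()
    valid = flat >= 0
    cross = np.real(f1 * np.conj(f2)).ravel()[valid]
    p1 = (np.abs(f1) ** 2).ravel()[valid]
    p2 = (np.abs(f2) ** 2).ravel()[valid]
    bins = flat[valid]

    num = np.bincount(bins, weights=cross, minlength=n_rings)
    d1 = np.bincount(bins, weights=p1, minlength=n_rings)
    d2 = np.bincount(bins, weights=p2, minlength=n_rings)
    counts = np.bincount(bins, minlength=n_rings)

    keep = counts > 0
    num, d1, d2, counts = num[keep], d1[keep], d2[keep], counts[keep]
    radii = ((np.arange(n_rings) + 0.5) * rw)[keep]

    denom = np.sqrt(d1 * d2)
    values = np.zeros_like(num)
    ok = denom > 0
    values[ok] = num[ok] / denom[ok]
    if np.any(~ok):
        logger.debug("FRC: %d ring(s) with zero power set to 0", int((~ok).sum()))
    return FRCCurve(radii, values, counts, float(values.mean()))


def detect_artifactual_slices(
    stack: ImageStack,
    log_sigma: float = DEFAULT_LOG_SIGMA,
    rule: str = "robust_z",
    k: float = 3.0,
    absolute_cutoff: Optional[float] = None,
    rel_frac: float = 0.5,
) -> SliceQualityReport:
    """Flag slices whose sharpness falls below a robust or absolute cutoff.

    ``robust_z`` flags slice i when ``sharpness_i < median - k * MAD`` and
    requires at least 5 slices; ``absolute`` flags below a fixed cutoff.
    ``rolling_robust_z`` first removes the slow depth trend of the
    sharpness series (running median, window 7) and applies the robust rule
    to the residuals — defocused slices are abrupt dips, whereas genuine
    content variation along z changes sharpness smoothly, so detrending
    keeps the MAD from being inflated on structurally heterogeneous stacks.
    ``relative`` flags a slice whose sharpness falls below ``rel_frac``
    times its running-median trend: a defocused slice loses well over half
    of its LoG response, while benign causes (content variation, subpixel
    resampling after drift correction) cost far less — this makes the rule
    robust on stacks that have already been through geometric corrections,
    and it is the restoration workflow's default.
    """
    vals = np.array([sharpness(sl, log_sigma) for sl in stack.data])
    if rule == "relative":
        if stack.n_z < 9:
            raise ValueError(
                "relative rule needs n_z >= 9; use rule='absolute' for "
                "shorter stacks"
            )
        if not 0 < rel_frac < 1:
            raise ValueError("rel_frac must be in (0, 1)")
        trend = ndimage.median_filter(vals, size=7, mode="nearest")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(trend > 0, vals / np.where(trend > 0, trend, 1.0),
                             1.0)
        flagged = sorted(int(z) for z in np.nonzero(ratio < rel_frac)[0])
        rule_info = {"rule": "relative", "rel_frac": rel_frac, "window": 7,
                     "log_sigma": log_sigma}
        return SliceQualityReport(vals, flagged, rule_info)
    if rule == "rolling_robust_z":
        if stack.n_z < 9:
            raise ValueError(
                "rolling_robust_z needs n_z >= 9; use rule='absolute' for "
                "shorter stacks"
            )
        trend = ndimage.median_filter(vals, size=7, mode="nearest")
        resid = vals - trend
        mad = float(np.median(np.abs(resid - np.median(resid))))
        cutoff_resid = float(np.median(resid)) - k * mad
        flagged = sorted(int(z) for z in np.nonzero(resid < cutoff_resid)[0])
        rule_info = {"rule": "rolling_robust_z", "k": k, "window": 7,
                     "mad": mad, "cutoff_residual": cutoff_resid,
                     "log_sigma": log_sigma}
        return SliceQualityReport(vals, flagged, rule_info)
    if rule == "robust_z":
        if stack.n_z < 5:
            raise ValueError(
                "robust_z rule needs n_z >= 5; use rule='absolute' for "
                "shorter stacks"
            )
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        cutoff = med - k * mad
        rule_info = {"rule": "robust_z", "k": k, "median": med, "mad": mad,
                     "cutoff": cutoff, "log_sigma": log_sigma}
    elif rule == "absolute":
        if absolute_cutoff is None:
            raise ValueError("absolute rule requires absolute_cutoff")
        cutoff = float(absolute_cutoff)
        rule_info = {"rule": "absolute", "cutoff": cutoff, "log_sigma": log_sigma}
    else:
        raise ValueError(f"unknown rule {rule!r}")
    flagged = sorted(int(z) for z in np.nonzero(vals < cutoff)[0])
    return SliceQualityReport(vals, flagged, rule_info)


def frc_validation(
    stack_before: ImageStack,
    stack_after: ImageStack,
    target_slices: Sequence[int],
    plane_range: int = DEFAULT_PLANE_RANGE,
    flagged: Optional[Iterable[int]] = None,
    ring_width: Optional[float] = None,
) -> Dict[int, Tuple[float, float]]:
    """Global FRC of each target slice against a clean reference plane,
    before and after restoration.

    The reference for target z is the slice at distance exactly
    ``plane_range``.  A reference must not itself be flagged, and a
    reference that is not even *adjacent* to any flagged plane is preferred
    (an adjacent one shares content with the very neighbors the inpainting
    drew from, which would bias the comparison).  A restoration is accepted
    when the after-score is at least the before-score.

    Returns ``{z: (global_before, global_after)}``; targets with no valid
    reference are skipped with a warning.
    """
    if plane_range < 1:
        raise ValueError("plane_range must be >= 1")
    if stack_before.shape != stack_after.shape:
        raise ValueError("before/after stacks must share a shape")
    flagged_set: Set[int] = set(int(z) for z in (flagged if flagged is not None
                                                 else target_slices))
    n_z = stack_before.n_z

    def isolated(c: int) -> bool:
        return not ({c - 1, c, c + 1} & flagged_set)

    out: Dict[int, Tuple[float, float]] = {}
    for t in target_slices:
        t = int(t)
        cands = [c for c in (t - plane_range, t + plane_range)
                 if 0 <= c < n_z and c not in flagged_set]
        ref = next((c for c in cands if isolated(c)), None)
        if ref is None and cands:
            ref = cands[0]
        if ref is None:
            warnings.warn(
                f"no valid FRC reference within +/-{plane_range} planes of "
                f"slice {t}; skipped"
            )
            continue
        ref_img = stack_after.data[ref]  # unflagged planes are untouched
        g_before = frc(stack_before.data[t], ref_img, ring_width).global_score
        g_after = frc(stack_after.data[t], ref_img, ring_width).global_score
        out[t] = (g_before, g_after)
    return out
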