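"""Synthetic FIB-SEM phantoms and parameterized degradations.

Real FIB-SEM stacks of the kind this package targets show a smooth,
low-contrast matrix with small bright, dense markers (e.g. gold beads on an
adjuvant matrix).  :func:`make_phantom` emulates this: a sum of broad 3-D
Gaussian blobs whose centroids drift smoothly along z (so adjacent slices
are correlated but not identical) plus small bright spheres of 2–4 px
radius.

:func:`degrade` injects the common acquisition artifacts — per-slice
translation drift, smooth additive charge gradients, vertical/horizontal
stripes ("curtaining"), per-slice defocus blur, mixed Poisson–Gaussian
noise and dropped slices — each controlled independently by a
:class:`DegradationSpec`, and returns the planted ground truth so recovery
can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core_io import ImageStack

__all__ = ["DegradationSpec", "make_phantom", "degrade", "make_textured_stack"]


@dataclass
class DegradationSpec:
    """Parameters of synthetic artifact injection.

    All amplitudes are fractions of the clean stack's dynamic range unless
    stated otherwise.  A default-constructed spec applies no degradation.

    Attributes
    ----------
    blur_slices
        Map z-index -> Gaussian blur sigma in pixels (defocus mimic).
    stripe_amplitude
        Peak amplitude of additive oriented stripes.
    stripe_period
        Stripe period in pixels along the axis perpendicular to the stripes.
    stripe_orientation
        ``"vertical"`` stripes run along y (curtaining from top-down
        milling); ``"horizontal"`` along x.
    drift_step_std
        Standard deviation in pixels of the per-slice random-walk drift step.
    charge_gradient_amplitude
        Amplitude of the smooth additive intensity field (charge mimic).
    noise
        ``(gaussian_std, poisson_scale)``; ``poisson_scale`` is the expected
        count at intensity 1.0 (0 disables shot noise).
    dropped_slices
        z-indices zero-filled to mimic unrecoverable/deleted acquisitions.
    seed
        RNG seed; the same seed always yields the identical degraded stack.
    """

    blur_slices: Dict[int, float] = field(default_factory=dict)
    stripe_amplitude: float = 0.0
    stripe_period: float = 8.0
    stripe_orientation: str = "vertical"
    drift_step_std: float = 0.0
    charge_gradient_amplitude: float = 0.0
    noise: Tuple[float, float] = (0.0, 0.0)
    dropped_slices: List[int] = field(default_factory=list)
    seed: int = 0

    def validate(self, n_z: Optional[int] = None) -> None:
        if self.stripe_amplitude < 0 or self.charge_gradient_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.drift_step_std < 0:
            raise ValueError("drift_step_std must be >= 0")
        if self.stripe_period <= 0:
            raise ValueError("stripe_period must be > 0")
        if self.stripe_orientation not in ("vertical", "horizontal"):
            raise ValueError("stripe_orientation must be vertical|horizontal")
        if any(s < 0 for s in self.noise):
            raise ValueError("noise levels must be >= 0")
        if any(sig <= 0 for sig in self.blur_slices.values()):
            raise ValueError("blur sigmas must be > 0")
        if n_z is not None:
            bad = [z for z in list(self.blur_slices) + list(self.dropped_slices)
                   if not 0 <= int(z) < n_z]
            if bad:
                raise ValueError(f"slice indices out of range: {bad}")


def make_phantom(
    shape: Tuple[int, int, int] = (40, 64, 64),
    n_blobs: int = 12,
    bead_fraction: float = 0.01,
    seed: int = 0,
    blob_drift: float = 0.15,
) -> ImageStack:
    """Generate a smooth blob + bright-bead phantom stack.

    Parameters
    ----------
    shape
        ``(n_z, n_y, n_x)``, at least ``(8, 32, 32)``.
    n_blobs
        Number of broad matrix blobs.  Centroids drift smoothly in z so
        neighboring slices are highly correlated but not identical.
    bead_fraction
        Bead density: the number of beads is ``bead_fraction * n_y * n_x``,
        spread through the volume.
    seed
        RNG seed; fully deterministic.
    blob_drift
        Maximum in-plane centroid velocity of the matrix blobs in px/slice.
        The default models the slow structural change of a well-sampled
        volume; note that coherent structural motion is physically
        indistinguishable from stage drift, so registration fixtures keep
        it small while interpolation fixtures may raise it.

    Returns
    -------
    ImageStack with intensities in [0, 1] over a 0.1 background.
    """
    n_z, n_y, n_x = (int(s) for s in shape)
    if n_z < 8 or n_y < 32 or n_x < 32:
        raise ValueError(f"phantom shape must be >= (8, 32, 32), got {shape}")
    rng = np.random.default_rng(seed)
    vol = np.full((n_z, n_y, n_x), 0.1, dtype=np.float64)

    zz = np.arange(n_z, dtype=np.float64)
    yy = np.arange(n_y, dtype=np.float64)[:, None]
    xx = np.arange(n_x, dtype=np.float64)[None, :]

    for _ in range(int(n_blobs)):
        cy0 = rng.uniform(0.15 * n_y, 0.85 * n_y)
        cx0 = rng.uniform(0.15 * n_x, 0.85 * n_x)
        cz = rng.uniform(0, n_z)
        sig_y = rng.uniform(4.0, 0.15 * n_y)
        sig_x = rng.uniform(4.0, 0.15 * n_x)
        sig_z_lo = min(4.0, 0.35 * n_z)
        sig_z = rng.uniform(sig_z_lo, max(0.4 * n_z, sig_z_lo + 1.0))
        amp = rng.uniform(0.15, 0.45)
        # smooth in-plane centroid drift: linear + sinusoidal component
        vy, vx = rng.uniform(-blob_drift, blob_drift, size=2)
        ay, ax = rng.uniform(0.0, 4.0 * blob_drift, size=2)
        period = rng.uniform(1.5 * n_z, 4.0 * n_z)
        phase = rng.uniform(0, 2 * np.pi)
        cy = cy0 + vy * zz + ay * np.sin(2 * np.pi * zz / period + phase)
        cx = cx0 + vx * zz + ax * np.cos(2 * np.pi * zz / period + phase)
        z_env = amp * np.exp(-0.5 * ((zz - cz) / sig_z) ** 2)
        for z in range(n_z):
            if z_env[z] < 1e-4:
                continue
            vol[z] += z_env[z] * np.exp(
                -0.5 * (((yy - cy[z]) / sig_y) ** 2 + ((xx - cx[z]) / sig_x) ** 2)
            )

    n_beads = int(round(bead_fraction * n_y * n_x))
    for _ in range(n_beads):
        bz = rng.uniform(2, n_z - 2)
        by = rng.uniform(4, n_y - 4)
        bx = rng.uniform(4, n_x - 4)
        # beads must persist across several planes for plane-offset FRC
        # comparisons to carry signal (the validation protocol assumes
        # structures outlive a plane_range of 3)
        r = rng.uniform(3.0, 5.0)
        amp = rng.uniform(0.7, 1.0)
        z0, z1 = max(0, int(bz - r - 2)), min(n_z, int(bz + r + 3))
        y0, y1 = max(0, int(by - r - 2)), min(n_y, int(by + r + 3))
        x0, x1 = max(0, int(bx - r - 2)), min(n_x, int(bx + r + 3))
        zl = np.arange(z0, z1, dtype=np.float64)[:, None, None]
        yl = np.arange(y0, y1, dtype=np.float64)[None, :, None]
        xl = np.arange(x0, x1, dtype=np.float64)[None, None, :]
        d2 = ((zl - bz) ** 2 + (yl - by) ** 2 + (xl - bx) ** 2) / r**2
        # supergaussian profile: flat core, soft ~1 px edge
        vol[z0:z1, y0:y1, x0:x1] += amp * np.exp(-(d2**2))

    np.clip(vol, 0.0, 1.0, out=vol)
    return ImageStack(vol)


def make_textured_stack(
    n_z: int = 50,
    shape: Tuple[int, int] = (64, 64),
    seed: int = 0,
    texture_sigma: float = 1.5,
) -> ImageStack:
    """Stack of i.i.d. textured slices sharing the same statistics.

    Each slice is an independent smoothed-noise field standardized to mean
    0.5 and standard deviation 0.15 (standardizing by the slice std keeps
    the per-slice statistics far tighter than min/max rescaling, whose
    extremes fluctuate).  Useful for sharpness/detection studies where the
    sharpness of clean slices must be tightly distributed.
    """
    rng = np.random.default_rng(seed)
    n_y, n_x = shape
    data = np.empty((n_z, n_y, n_x))
    for z in range(n_z):
        sl = ndimage.gaussian_filter(rng.normal(size=(n_y, n_x)), texture_sigma)
        data[z] = 0.5 + 0.15 * (sl - sl.mean()) / sl.std()
    return ImageStack(data)


def _charge_field(n_y: int, n_x: int, amplitude: float, rng) -> np.ndarray:
    """Smooth planar + quadratic additive field normalized to peak amplitude."""
    y = np.linspace(-1, 1, n_y)[:, None]
    x = np.linspace(-1, 1, n_x)[None, :]
    a, b = rng.uniform(-1, 1, size=2)
    c = rng.uniform(-0.5, 0.5)
    q = rng.uniform(-0.5, 0.5)
    f = a * x + b * y + c * x * y + q * (x**2 + y**2)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return amplitude * f


def _stripe_pattern(
    n: int, period: float, amplitude: float, rng
) -> np.ndarray:
    """1-D curtaining profile: sinusoid plus random per-line offsets."""
    t = np.arange(n, dtype=np.float64)
    phase = rng.uniform(0, 2 * np.pi)
    prof = 0.7 * np.sin(2 * np.pi * t / period + phase)
    prof += 0.3 * rng.standard_normal(n)
    return amplitude * prof


def degrade(
    stack: ImageStack, spec: DegradationSpec
) -> Tuple[ImageStack, dict]:
    """Apply the degradations in `spec`, returning planted ground truth.

    Order: drift -> charge gradient -> stripes -> per-slice blur -> noise ->
    slice drops.  Every step can also be applied alone by leaving the others
    at their defaults.

    Returns
    -------
    degraded
        Degraded copy of the input stack.
    truth
        Dict with ``clean`` (the untouched input stack), ``shifts`` (planted
        per-slice (dy, dx) drift vs slice 0), ``blur_slices``,
        ``dropped_slices`` and the ``spec`` echo.
    """
    spec.validate(n_z=stack.n_z)
    rng = np.random.default_rng(spec.seed)
    data = stack.data.copy()
    n_z, n_y, n_x = data.shape
    dyn = data.max() - data.min()
    if dyn == 0:
        dyn = 1.0

    shifts = np.zeros((n_z, 2))
    if spec.drift_step_std > 0:
        steps = rng.normal(0.0, spec.drift_step_std, size=(n_z, 2))
        steps[0] = 0.0
        shifts = np.cumsum(steps, axis=0)
        for z in range(1, n_z):
            data[z] = ndimage.shift(
                data[z], shifts[z], order=3, mode="nearest"
            )

    if spec.charge_gradient_amplitude > 0:
        field2d = _charge_field(
            n_y, n_x, spec.charge_gradient_amplitude * dyn, rng
        )
        data += field2d[np.newaxis, :, :]

    if spec.stripe_amplitude > 0:
        amp = spec.stripe_amplitude * dyn
        for z in range(n_z):
            if spec.stripe_orientation == "vertical":
                prof = _stripe_pattern(n_x, spec.stripe_period, amp, rng)
                data[z] += prof[np.newaxis, :]
            else:
                prof = _stripe_pattern(n_y, spec.stripe_period, amp, rng)
                data[z] += prof[:, np.newaxis]

    for z, sigma in sorted(spec.blur_slices.items()):
        data[int(z)] = ndimage.gaussian_filter(data[int(z)], sigma, mode="mirror")

    g_std, p_scale = spec.noise
    if p_scale > 0:
        base = np.clip(data, 0.0, None)
        data = rng.poisson(base * p_scale).astype(np.float64) / p_scale
    if g_std > 0:
        data += rng.normal(0.0, g_std * dyn, size=data.shape)

    for z in spec.dropped_slices:
        data[int(z)] = 0.0

    truth = {
        "clean": stack.copy(),
        "shifts": shifts,
        "blur_slices": dict(spec.blur_slices),
        "dropped_slices": list(spec.dropped_slices),
        "spec": spec,
    }
    return stack.with_data(data), truth
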