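"""End-to-end restoration workflow and parallel per-slice execution.

The workflow applies the stages in a fixed order — charge correction,
destriping, drift alignment, deconvolution, artifactual-slice detection,
slice removal + inpainting, FRC validation — with geometric corrections
placed before PSF estimation (a drifting or striped slice would bias the
spectral fit).  Every stage can be toggled; the report echoes the full
parameter set for provenance and records, per replaced slice, the global
FRC against its reference plane before and after inpainting.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .core_io import ImageStack, mask_from_slices
from .corrections import (
    DeconvolutionParams,
    StripeFilterSpec,
    align_stack,
    estimate_psf,
    remove_stripes,
    richardson_lucy,
    rolling_ball,
)
from .inpainting import InpaintParams, inpaint
from .quality import (
    DEFAULT_LOG_SIGMA,
    DEFAULT_PLANE_RANGE,
    SliceQualityReport,
    detect_artifactual_slices,
    frc_validation,
)

__all__ = [
    "RestorationPlan",
    "RestorationReport",
    "run_restoration",
    "parallel_map_slices",
    "SliceOp",
    "charge_op",
    "destripe_op",
    "deconvolve_op",
]

logger = logging.getLogger(__name__)

STAGE_ORDER = ("charge", "destripe", "align", "deconvolve", "detect",
               "inpaint", "validate")


@dataclass
class RestorationPlan:
    """Stage toggles and per-stage parameters of the restoration workflow."""

    charge: bool = True
    charge_radius: float = 25.0
    destripe: bool = False
    destripe_spec: StripeFilterSpec = field(default_factory=StripeFilterSpec)
    align: bool = False
    align_levels: int = 3
    deconvolve: bool = True
    deconv_params: DeconvolutionParams = field(
        default_factory=DeconvolutionParams
    )
    psf_sigma: Optional[float] = None  # None = estimate per slice
    detect: bool = True
    detect_log_sigma: float = DEFAULT_LOG_SIGMA
    detect_rule: str = "relative"
    detect_k: float = 3.0
    detect_rel_frac: float = 0.5
    inpaint: bool = True
    inpaint_params: InpaintParams = field(default_factory=InpaintParams)
    validate: bool = True
    plane_range: int = DEFAULT_PLANE_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if not any(
            getattr(self, s)
            for s in ("charge", "destripe", "align", "deconvolve", "detect",
                      "inpaint", "validate")
        ):
            raise ValueError("at least one stage must be enabled")
        if (self.inpaint or self.validate) and not self.detect:
            raise ValueError("inpaint/validate require the detect stage")
        if self.plane_range < 1:
            raise ValueError("plane_range must be >= 1")

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if is_dataclass(v):
                d[k] = {
                    kk: (list(vv) if isinstance(vv, (tuple, np.ndarray)) else vv)
                    for kk, vv in v.__dict__.items()
                }
            else:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RestorationPlan":
        d = dict(d)
        if "destripe_spec" in d and isinstance(d["destripe_spec"], dict):
            d["destripe_spec"] = StripeFilterSpec(**d["destripe_spec"])
        if "deconv_params" in d and isinstance(d["deconv_params"], dict):
            d["deconv_params"] = DeconvolutionParams(**d["deconv_params"])
        if "inpaint_params" in d and isinstance(d["inpaint_params"], dict):
            d["inpaint_params"] = InpaintParams(**d["inpaint_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RestorationPlan":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RestorationReport:
    """Everything a reviewer needs to audit one restoration run."""

    stage_status: Dict[str, str] = field(default_factory=dict)
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    quality_before: Optional[SliceQualityReport] = None
    quality_after: Optional[SliceQualityReport] = None
    frc_scores: Dict[int, Tuple[float, float]] = field(default_factory=dict)
    replaced_slices: List[int] = field(default_factory=list)
    plan_echo: dict = field(default_factory=dict)

    @property
    def all_replacements_accepted(self) -> bool:
        """True when every replaced slice's FRC did not decrease."""
        return all(after >= before for before, after in self.frc_scores.values())

    def to_dict(self) -> dict:
        def qr(q):
            if q is None:
                return None
            return {
                "sharpness": [float(s) for s in q.sharpness],
                "flagged": list(q.flagged),
                "threshold_rule": q.threshold_rule,
            }

        return {
            "stage_status": self.stage_status,
            "stage_seconds": self.stage_seconds,
            "quality_before": qr(self.quality_before),
            "quality_after": qr(self.quality_after),
            "frc_scores": {
                str(z): [float(b), float(a)]
                for z, (b, a) in self.frc_scores.items()
            },
            "replaced_slices": list(self.replaced_slices),
            "all_replacements_accepted": self.all_replacements_accepted,
            "plan_echo": self.plan_echo,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


class _StageError(RuntimeError):
    pass


def _run_stage(report: RestorationReport, name: str, fn: Callable):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:
        report.stage_status[name] = f"error: {exc}"
        raise _StageError(f"stage {name!r} failed: {exc}") from exc
    dt = time.perf_counter() - t0
    report.stage_status[name] = "ok"
    report.stage_seconds[name] = round(dt, 4)
    logger.info("stage %s finished in %.2fs", name, dt)
    return result


def run_restoration(
    stack: ImageStack, plan: RestorationPlan
) -> Tuple[ImageStack, RestorationReport]:
    """Run the enabled stages in fixed order on a copy of the stack.

    Deterministic for a given (stack, plan).  Any stage error aborts the
    run with the stage name; no partial output is returned.
    """
    report = RestorationReport(plan_echo=plan.to_dict())
    data = stack.data.copy()

    if plan.charge:
        def _charge():
            return np.stack([rolling_ball(sl, plan.charge_radius)[0]
                             for sl in data])
        data = _run_stage(report, "charge", _charge)

    if plan.destripe:
        def _destripe():
            return np.stack([remove_stripes(sl, plan.destripe_spec)
                             for sl in data])
        data = _run_stage(report, "destripe", _destripe)

    if plan.align:
        def _align():
            aligned, _ = align_stack(stack.with_data(data), plan.align_levels)
            return aligned.data
        data = _run_stage(report, "align", _align)

    if plan.deconvolve:
        def _deconv():
            out = np.empty_like(data)
            for i, sl in enumerate(data):
                if plan.psf_sigma is not None:
                    psf = estimate_psf_from_sigma(plan.psf_sigma)
                else:
                    psf = estimate_psf(sl)
                out[i] = richardson_lucy(sl, psf, plan.deconv_params)
            return out
        data = _run_stage(report, "deconvolve", _deconv)

    flagged: List[int] = []
    if plan.detect:
        def _detect():
            return detect_artifactual_slices(
                stack.with_data(data), plan.detect_log_sigma,
                plan.detect_rule, plan.detect_k,
                rel_frac=plan.detect_rel_frac,
            )
        q = _run_stage(report, "detect", _detect)
        report.quality_before = q
        flagged = list(q.flagged)

    pre_inpaint = data
    if plan.inpaint and flagged:
        def _inpaint():
            mask = mask_from_slices(data.shape, flagged)
            return inpaint(stack.with_data(data), mask,
                           plan.inpaint_params).data
        data = _run_stage(report, "inpaint", _inpaint)
        report.replaced_slices = sorted(flagged)

    if plan.validate and report.replaced_slices:
        def _validate():
            return frc_validation(
                stack.with_data(pre_inpaint), stack.with_data(data),
                report.replaced_slices, plan.plane_range,
                flagged=report.replaced_slices,
            )
        report.frc_scores = _run_stage(report, "validate", _validate)

    if plan.detect and (plan.inpaint or plan.deconvolve):
        report.quality_after = detect_artifactual_slices(
            stack.with_data(data), plan.detect_log_sigma,
            plan.detect_rule, plan.detect_k,
            rel_frac=plan.detect_rel_frac,
        )

    return stack.with_data(data), report


def estimate_psf_from_sigma(sigma: float):
    from .corrections import PSFModel

    return PSFModel(sigma=sigma)


# ---------------------------------------------------------------------------
# parallel per-slice execution
# ---------------------------------------------------------------------------

class SliceOp:
    """A pure per-slice operation (2-D in, 2-D out), safe to parallelize.

    Pickles cleanly (module-level function plus keyword arguments), carries
    the ``slicewise`` marker that :func:`parallel_map_slices` requires, and
    holds no mutable shared state.
    """

    slicewise = True

    def __init__(self, func: Callable, **kwargs):
        self.func = func
        self.kwargs = kwargs

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.func(image, **self.kwargs)

    def __repr__(self) -> str:
        return f"SliceOp({self.func.__name__}, {self.kwargs})"


def _charge_slice(image, radius):
    return rolling_ball(image, radius)[0]


def _deconv_slice(image, sigma, params):
    from .corrections import PSFModel

    psf = PSFModel(sigma=sigma) if sigma is not None else estimate_psf(image)
    return richardson_lucy(image, psf, params)


def charge_op(radius: float = 25.0) -> SliceOp:
    return SliceOp(_charge_slice, radius=radius)


def destripe_op(spec: Optional[StripeFilterSpec] = None) -> SliceOp:
    return SliceOp(remove_stripes, spec=spec or StripeFilterSpec())


def deconvolve_op(
    sigma: Optional[float] = None,
    params: Optional[DeconvolutionParams] = None,
) -> SliceOp:
    return SliceOp(_deconv_slice, sigma=sigma,
                   params=params or DeconvolutionParams())


def parallel_map_slices(
    op: Callable[[np.ndarray], np.ndarray],
    stack: ImageStack,
    n_workers: int = 1,
) -> ImageStack:
    """Apply a pure per-slice operation to every slice, possibly in parallel.

    The result is bitwise identical regardless of ``n_workers`` because each
    slice is processed by the same code with no shared mutable state; the
    first worker error is propagated and the remaining tasks cancelled.
    Only operations carrying the ``slicewise`` marker (see :class:`SliceOp`)
    are accepted — stack-level operations such as alignment or 3-D
    inpainting are not slice-separable.
    """
    if not getattr(op, "slicewise", False):
        raise ValueError(
            "parallel_map_slices requires a slicewise operation "
            "(wrap a pure per-slice function in SliceOp)"
        )
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    slices = list(stack.data)
    if n_workers == 1:
        results = [op(sl) for sl in slices]
    else:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            try:
                results = list(pool.map(op, slices))
            except Exception:
                pool.shutdown(wait=False, cancel_futures=True)
                raise
    return stack.with_data(np.stack(results))
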