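"""Raw stack -> corrected per-frame metric time series.

Processing order mirrors the measurement chain: optional pixel-wise dark
correction (reference frames taken with the cooled sensor in the dark),
optional integration-time rebinning, ROI extraction, pixel-by-pixel
background correction against a same-size background window, then one
metric record per frame per ROI at the chosen analysis depth.  All
subtractions clamp at zero — photon counts are non-negative — and the
whole path is deterministic: identical inputs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import FrameStack, RegionOfInterest, extract_roi
from .metrics import MetricResult, compute_metrics

log = logging.getLogger("ewsfd")

#: Widest accumulator the rebinner will declare as container depth.
ACCUMULATOR_BITS = 32

#: Columns of the serialised metric table, one row per ROI per frame.
SERIES_COLUMNS = (
    "time_s",
    "roi",
    "entropy_bits",
    "sfd_esr",
    "sfd_dsr",
    "ew_sfd",
    "S",
    "n",
    "floored_levels",
)


@dataclasses.dataclass
class CorrectionSpec:
    """Corrections to apply before metric computation.

    ``dark`` is a per-pixel reference: a dark FrameStack (reduced to its
    per-pixel mean, rounded to the nearest count) or a ready (H, W) frame.
    ``background_roi`` names the window whose pixels are subtracted
    positionally from every same-size non-background ROI.
    ``scalar_background`` switches to subtracting the background window's
    per-frame mean instead of positional pairing (off by default).
    """

    dark: Optional[Union[FrameStack, np.ndarray]] = None
    background_roi: Optional[RegionOfInterest] = None
    scalar_background: bool = False


@dataclasses.dataclass
class MetricSeries:
    """Per-frame metric results for one ROI, with processing provenance."""

    roi_name: str
    times: np.ndarray
    results: list[MetricResult]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.results):
            raise ValidationError("times and results must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                float(t),
                self.roi_name,
                r.entropy_bits,
                r.sfd_esr,
                r.sfd_dsr,
                r.ew_sfd,
                r.S,
                r.n,
                r.floored_levels,
            )
            for t, r in zip(self.times, self.results)
        ]
        return pd.DataFrame(rows, columns=list(SERIES_COLUMNS))


def series_to_frame(series: Sequence[MetricSeries]) -> pd.DataFrame:
    """Concatenate several ROI series into one long table."""
    return pd.concat([s.to_frame() for s in series], ignore_index=True)


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

def _dark_frame(dark: Union[FrameStack, np.ndarray]) -> np.ndarray:
    """Reduce a dark reference to one per-pixel integer frame."""
    if isinstance(dark, FrameStack):
        return np.rint(dark.frames.mean(axis=0)).astype(np.int64)
    arr = np.asarray(dark)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.rint(arr)
    return arr.astype(np.int64)


def dark_correct(stack: FrameStack, dark: Union[FrameStack, np.ndarray]) -> FrameStack:
    """Subtract a per-pixel dark reference from every frame, clamped at 0."""
    ref = _dark_frame(dark)
    if ref.shape != stack.frames.shape[1:]:
        raise ValidationError(
            f"dark reference shape {ref.shape} does not match "
            f"frame shape {stack.frames.shape[1:]}"
        )
    out = np.maximum(stack.frames.astype(np.int64) - ref, 0)
    return FrameStack(
        out,
        container_bits=stack.container_bits,
        frame_interval=stack.frame_interval,
    )


def background_correct(
    stack: FrameStack,
    embryo_roi: RegionOfInterest,
    background_roi: RegionOfInterest,
    *,
    scalar: bool = False,
) -> FrameStack:
    """Pixel-by-pixel background subtraction of one ROI against another.

    The two windows must be the same size, inside the frame, and disjoint;
    pixels are paired by position within each window.  ``scalar=True``
    subtracts the background window's per-frame mean count instead.
    Returns the corrected T x height x width sub-stack, clamped at 0.
    """
    if embryo_roi.shape != background_roi.shape:
        raise ValidationError(
            f"ROI sizes differ: {embryo_roi.shape} vs {background_roi.shape}"
        )
    if embryo_roi.overlaps(background_roi):
        raise ValidationError("embryo and background ROIs overlap")
    emb = extract_roi(stack, embryo_roi).frames.astype(np.int64)
    bg = extract_roi(stack, background_roi).frames.astype(np.int64)
    if scalar:
        axes = tuple(range(1, bg.ndim))
        ref = np.rint(bg.mean(axis=axes)).astype(np.int64)
        ref = ref.reshape((-1,) + (1,) * (bg.ndim - 1))
    else:
        ref = bg
    out = np.maximum(emb - ref, 0)
    return FrameStack(
        out,
        container_bits=stack.container_bits,
        frame_interval=stack.frame_interval,
    )


# ---------------------------------------------------------------------------
# rebinning and depth
# ---------------------------------------------------------------------------

def rebin_integration_time(stack: FrameStack, k: int) -> FrameStack:
    """Merge each run of ``k`` frames into one by elementwise summation.

    Emulates a ``k``-times longer integration time.  A trailing partial bin
    is dropped so every output frame covers the same interval.  Sums
    accumulate in 64-bit integers; the declared container depth becomes the
    depth of the largest summed value (capped at the accumulator width).
    """
    if k < 1:
        raise ValidationError(f"rebin factor must be >= 1, got {k}")
    if k > stack.n_frames:
        raise ValidationError(
            f"rebin factor {k} exceeds the {stack.n_frames}-frame stack"
        )
    nbins = stack.n_frames // k
    kept = stack.frames[: nbins * k].astype(np.int64)
    summed = kept.reshape((nbins, k) + kept.shape[1:]).sum(axis=1)
    bits = max(1, int(summed.max()).bit_length())
    return FrameStack(
        summed,
        container_bits=min(bits, ACCUMULATOR_BITS),
        frame_interval=stack.frame_interval * k,
    )


def effective_data_depth(stack: Union[FrameStack, np.ndarray]) -> int:
    """Smallest bit depth S with every pixel value below ``2**S`` (>= 1).

    Recordings saved in a 16-bit container often hold far shallower data;
    the analysis depth defaults to this effective depth.
    """
    arr = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    if arr.size == 0:
        raise ValidationError("cannot take the data depth of an empty stack")
    return max(1, int(arr.max()).bit_length())


def num_frames(duration_s: float, frame_interval_s: float = 60.0) -> int:
    """Whole frames acquired in ``duration_s`` at one frame per interval."""
    if frame_interval_s <= 0:
        raise ValidationError("frame interval must be positive")
    return int(duration_s // frame_interval_s)


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

def metric_time_series(
    stack: FrameStack,
    rois: Sequence[RegionOfInterest],
    corrections: Optional[CorrectionSpec] = None,
    S: Union[int, str] = "auto",
    *,
    rebin: int = 1,
    exclude_zeros: bool = False,
) -> list[MetricSeries]:
    """Corrected per-frame metric series for each ROI.

    Per ROI: dark-correct the stack (if a dark reference is given), rebin,
    extract the window, background-correct non-background ROIs against the
    spec's background window, then compute one MetricResult per frame.
    ``S="auto"`` analyses each ROI at the effective data depth of its own
    corrected sub-stack (floored at 2); an integer fixes the depth for all
    ROIs.  The background ROI is its own reference and is never
    background-subtracted.
    """
    corrections = corrections or CorrectionSpec()
    if corrections.dark is not None:
        stack = dark_correct(stack, corrections.dark)
        log.info("applied per-pixel dark correction")
    if rebin != 1:
        stack = rebin_integration_time(stack, rebin)
        log.info("rebinned by %d -> %d frames", rebin, stack.n_frames)

    bg_roi = corrections.background_roi
    out: list[MetricSeries] = []
    for roi in rois:
        subtract_bg = (
            bg_roi is not None and roi.role != "background" and roi != bg_roi
        )
        if subtract_bg:
            sub = background_correct(
                stack, roi, bg_roi, scalar=corrections.scalar_background
            )
        else:
            sub = extract_roi(stack, roi)
        depth = (
            max(2, effective_data_depth(sub)) if S == "auto" else int(S)
        )
        results = [
            compute_metrics(sub.frames[t], depth, exclude_zeros=exclude_zeros)
            for t in range(sub.n_frames)
        ]
        floored = sum(r.floored_levels for r in results)
        log.info(
            "ROI %s: depth S=%d, background=%s, %d floored level terms",
            roi.name or roi.role,
            depth,
            "yes" if subtract_bg else "no",
            floored,
        )
        out.append(
            MetricSeries(
                roi_name=roi.name or roi.role,
                times=sub.times,
                results=results,
                provenance={
                    "dark_corrected": corrections.dark is not None,
                    "background_roi": bg_roi.name if subtract_bg and bg_roi else None,
                    "scalar_background": corrections.scalar_background,
                    "rebin": rebin,
                    "S": depth,
                    "exclude_zeros": exclude_zeros,
                },
            )
        )
    return out
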