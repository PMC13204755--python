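"""Three-frame threshold detection of blinking transients.

A single emitter switching between emissive (ON) and dark (OFF) states
produces rapid frame-to-frame intensity changes at its pixel that a slowly
varying background cannot.  The detector scans every pixel trace with a
three-frame window (F1, F2, F3), forms the absolute differences
``d1 = |F1 - F2|`` and ``d2 = |F2 - F3|``, and declares a detection at the
first window where **both** differences strictly exceed the threshold tau;
the scan for that pixel then stops.  The digital readout N is the number
of pixels detected at least once in the movie — the counting unit is the
pixel, not a clustered molecule.

Frame indices on every external surface are 1-based: the earliest possible
hit is t=1 and the latest is t=T-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filtering import FilterParams, median_filter_stack
from .stack import ImageStack, as_signed


class TraceTooShortError(ValueError):
    """Fewer than three frames: the three-frame pattern is undefined."""


@dataclass(frozen=True)
class DetectorParams:
    """Detection threshold tau (same ADU units as the stack) and window size.

    The window is fixed at 3; the criterion is defined on exactly
    (F1, F2, F3).  The comparison is strict: ``d > tau``, so boundary
    equality does not detect.
    """

    tau: float
    window: int = 3

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau) or self.tau < 0:
            raise ValueError(f"tau must be finite and >= 0; got {self.tau}")
        if self.window != 3:
            raise ValueError("the detection criterion is defined on a 3-frame window")


@dataclass
class DetectionResult:
    """Binary mask of detected pixels plus the digital count N.

    ``first_hit`` holds the 1-based frame index of the earliest satisfying
    window per pixel, with 0 where the pixel never detected (mask False).
    """

    mask: np.ndarray
    first_hit: np.ndarray
    count: int
    tau_used: float
    source_filtered: bool

    def __post_init__(self) -> None:
        if self.count != int(self.mask.sum()):
            raise ValueError("count must equal the number of True mask entries")
        if self.mask.shape != self.first_hit.shape:
            raise ValueError("mask and first_hit shapes differ")

    @property
    def n_detected(self) -> int:
        return self.count

    def first_hit_histogram(self) -> dict[int, int]:
        """Counts of detections per (1-based) first-hit frame index."""
        hits = self.first_hit[self.mask]
        values, counts = np.unique(hits, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


def detect_pixel_trace(trace, tau: float) -> tuple[bool, int | None]:
    """Scan one pixel's intensity trace for the three-frame transient pattern.

    Returns ``(detected, first_hit)`` where ``first_hit`` is the 1-based
    index of the earliest window with ``d1 > tau`` and ``d2 > tau``, or
    ``None`` if no window qualifies.  The scan stops at the first hit.
    """
    arr = as_signed(np.asarray(trace))
    if arr.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    T = arr.shape[0]
    if T < 3:
        raise TraceTooShortError(f"trace has {T} frames; need at least 3")
    if not np.all(np.isfinite(arr)):
        raise ValueError("trace contains non-finite values")

    for t in range(T - 2):
        f1, f2, f3 = arr[t], arr[t + 1], arr[t + 2]
        d1 = abs(f1 - f2)
        d2 = abs(f2 - f3)
        if d1 > tau and d2 > tau:
            return True, t + 1
    return False, None


def detect_stack(stack: ImageStack, params: DetectorParams) -> DetectionResult:
    """Apply the three-frame criterion to every pixel of the movie.

    Vectorized over the field of view; equivalent to calling
    :func:`detect_pixel_trace` at every (y, x).  Deterministic, and the
    input stack is never modified.
    """
    data = as_signed(stack.data)
    if stack.n_frames < 3:
        raise TraceTooShortError(
            f"stack has {stack.n_frames} frames; detection needs T >= 3"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("stack contains non-finite values")

    diffs = np.abs(np.diff(data, axis=0))          # (T-1, H, W)
    hits = (diffs[:-1] > params.tau) & (diffs[1:] > params.tau)  # (T-2, H, W)
    mask = hits.any(axis=0)
    # argmax finds the earliest satisfying window; +1 converts to 1-based.
    first_hit = np.where(mask, hits.argmax(axis=0).astype(np.int32) + 1, 0).astype(
        np.int32
    )
    return DetectionResult(
        mask=mask,
        first_hit=first_hit,
        count=int(mask.sum()),
        tau_used=params.tau,
        source_filtered=stack.is_filtered,
    )


def detect_oracle(stack: ImageStack, params: DetectorParams) -> DetectionResult:
    """Literal loop transcription of the detection rule; the equivalence oracle.

    Iterates pixel by pixel and window by window with no vectorization and
    no early exit other than the per-pixel stop.  Intended for small stacks
    only.
    """
    if stack.n_frames < 3:
        raise TraceTooShortError(
            f"stack has {stack.n_frames} frames; detection needs T >= 3"
        )
    data = as_signed(stack.data)
    T, H, W = data.shape
    mask = np.zeros((H, W), dtype=bool)
    first_hit = np.zeros((H, W), dtype=np.int32)
    for y in range(H):
        for x in range(W):
            for t in range(T - 2):
                f1 = data[t, y, x]
                f2 = data[t + 1, y, x]
                f3 = data[t + 2, y, x]
                d1 = abs(f1 - f2)
                d2 = abs(f2 - f3)
                if d1 > params.tau and d2 > params.tau:
                    mask[y, x] = True
                    first_hit[y, x] = t + 1
                    break
    return DetectionResult(
        mask=mask,
        first_hit=first_hit,
        count=int(mask.sum()),
        tau_used=params.tau,
        source_filtered=stack.is_filtered,
    )


def run_pipeline(
    raw: ImageStack,
    filter_params: FilterParams | None = None,
    det_params: DetectorParams | None = None,
) -> DetectionResult:
    """Denoise then detect: the standard two-stage counting pipeline.

    Median-filters the raw movie with ``filter_params`` (default (1, 3, 3))
    and runs the threshold detector on the filtered stack, so detection
    operates on If(x, y, t).  The result records ``source_filtered=True``.
    """
    if det_params is None:
        raise ValueError("det_params (the threshold tau) is required")
    filtered = median_filter_stack(raw, filter_params or FilterParams())
    return detect_stack(filtered, det_params)
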