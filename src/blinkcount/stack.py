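"""Image-stack container and TIFF movie I/O.

A fluorescence movie is held in memory as a single 3-D intensity tensor
``I(t, y, x)`` — frame index first, then row, then column.  Every other
module in the package operates on this one representation, so the axis
convention is fixed here and converted exactly once, at the file boundary.
Raw camera data is typically unsigned integer (ADU); arithmetic elsewhere
promotes to a signed wide type via :func:`as_signed` because absolute
frame differences on unsigned dtypes silently wrap.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile


class StackError(Exception):
    """Base class for image-stack errors."""


class MissingFileError(StackError, FileNotFoundError):
    """The requested TIFF path does not exist."""


class EmptyStackError(StackError):
    """The TIFF file contains no pages (or a glob matched no files)."""


class MultiChannelError(StackError):
    """A page is RGB/multi-channel; only single-channel grayscale is supported."""


class RaggedPagesError(StackError):
    """Pages disagree in shape or dtype."""


class NonFiniteDataError(StackError):
    """Stack data contains NaN or infinity."""


@dataclass
class ImageStack:
    """A movie as a 3-D tensor indexed ``(frame t, row y, column x)``.

    Parameters
    ----------
    data
        Intensity tensor of shape ``(T, H, W)``; non-negative, finite.
    pixel_size
        Physical pixel pitch in micrometers (needed only for areal density).
    exposure_s
        Exposure per frame in seconds (metadata only).
    is_filtered
        ``True`` once denoising has been applied; freshly loaded raw
        movies carry ``False``.
    """

    data: np.ndarray
    pixel_size: float | None = None
    exposure_s: float | None = None
    is_filtered: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(
                f"stack data must have shape (T, H, W); got ndim={arr.ndim}"
            )
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "ImageStack":
        return replace(self, data=self.data.copy())


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_stack`: hard violations plus advisories."""

    violations: list[str] = field(default_factory=list)
    advisories: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations


def as_signed(data: np.ndarray) -> np.ndarray:
    """Promote intensities to a signed wide type for difference arithmetic.

    Unsigned integers become int64; floats become float64.  ``|a - b|`` on
    raw uint data wraps around zero, so every arithmetic consumer goes
    through this promotion.
    """
    arr = np.asarray(data)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int64)
    return arr.astype(np.float64)


def _resolve_pages(path: str | Path) -> list[Path]:
    """Expand a path, directory or glob into an ordered list of TIFF files."""
    p = Path(path)
    if p.is_dir():
        files = sorted(
            q for q in p.iterdir() if q.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise EmptyStackError(f"directory contains no TIFF files: {p}")
        return files
    if _glob.has_magic(str(path)):
        files = [Path(q) for q in sorted(_glob.glob(str(path)))]
        if not files:
            raise EmptyStackError(f"glob matched no files: {path}")
        return files
    if not p.exists():
        raise MissingFileError(f"no such file: {p}")
    return [p]


def load_stack(
    path: str | Path,
    *,
    pixel_size: float | None = None,
    exposure_s: float | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF movie (or a per-frame file sequence).

    ``path`` may be a single multi-page TIFF, a directory of one-frame
    TIFFs, or a glob pattern; multi-file sequences are concatenated in
    sorted filename order.  Frames keep file page order and intensities are
    preserved bit-exact.

    Raises
    ------
    MissingFileError, EmptyStackError, MultiChannelError, RaggedPagesError
    """
    files = _resolve_pages(path)

    frames: list[np.ndarray] = []
    for f in files:
        with tifffile.TiffFile(f) as tif:
            if len(tif.pages) == 0:
                raise EmptyStackError(f"TIFF has zero pages: {f}")
            for page in tif.pages:
                arr = page.asarray()
                if arr.ndim == 3:
                    raise MultiChannelError(
                        f"page with {arr.shape[-1]} channels in {f}; "
                        "only single-channel grayscale is supported"
                    )
                if arr.ndim != 2:
                    raise MultiChannelError(
                        f"page of dimensionality {arr.ndim} in {f}"
                    )
                frames.append(arr)

    shapes = {fr.shape for fr in frames}
    dtypes = {fr.dtype for fr in frames}
    if len(shapes) > 1:
        raise RaggedPagesError(f"pages have inconsistent shapes: {sorted(shapes)}")
    if len(dtypes) > 1:
        raise RaggedPagesError(
            f"pages have inconsistent dtypes: {sorted(map(str, dtypes))}"
        )

    data = np.stack(frames, axis=0)
    return ImageStack(
        data, pixel_size=pixel_size, exposure_s=exposure_s, is_filtered=False
    )


def save_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page grayscale TIFF (page count = T).

    Integer stacks round-trip bit-exact through :func:`load_stack`.
    """
    data = np.asarray(stack.data)
    if not np.all(np.isfinite(data)):
        raise NonFiniteDataError("stack contains non-finite values; cannot save")
    path = Path(path)
    parent = path.parent
    if parent and not parent.exists():
        raise StackError(f"output directory does not exist: {parent}")
    if parent and not os.access(parent, os.W_OK):
        raise StackError(f"output directory is not writable: {parent}")
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def validate_stack(stack: ImageStack) -> ValidationReport:
    """Check the stack invariants without mutating anything.

    Hard violations: wrong shape, empty axes, negative or non-finite
    intensities, a filtered flag set on load.  Advisories flag conditions
    that are legal here but break a downstream stage — notably ``T < 3``,
    which is too short for the three-frame detection window.
    """
    report = ValidationReport()
    data = np.asarray(stack.data)

    if data.ndim != 3:
        report.violations.append(f"data must be 3-D (T, H, W); got ndim={data.ndim}")
        return report
    t, h, w = data.shape
    if t < 1 or h < 1 or w < 1:
        report.violations.append(f"all dimensions must be >= 1; got shape {data.shape}")
    if data.size and not np.all(np.isfinite(as_signed(data))):
        report.violations.append("non-finite intensity (NaN or inf) present")
    elif data.size and np.any(as_signed(data) < 0):
        report.violations.append("negative intensity present")

    if t < 3:
        report.advisories.append(
            f"only {t} frame(s): too short for detection (detector needs T >= 3)"
        )
    return report
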