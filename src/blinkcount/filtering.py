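"""Median-filter denoising of movie stacks.

Blinking movies carry impulsive pixel-level noise on top of slowly varying
background.  The pipeline suppresses it with a 3-D median filter of kernel
``(1, 3, 3)``: the temporal axis is held fixed and each pixel is replaced
by the median of its 3x3 spatial neighborhood within its own frame.  A
nonlinear median preserves the sharp frame-to-frame transients the
detector relies on, where Gaussian or mean smoothing would blur them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .stack import ImageStack

#: scipy boundary mode -> numpy.pad mode, used by the brute-force oracle.
_PAD_MODE = {
    "reflect": "symmetric",  # edge sample repeated: (d c b a | a b c d)
    "mirror": "reflect",     # edge sample not repeated: (d c b | a b c d)
    "nearest": "edge",
    "wrap": "wrap",
    "constant": "constant",
}


@dataclass(frozen=True)
class FilterParams:
    """Median-filter configuration.

    kernel
        Odd window lengths along ``(t, y, x)``.  The default ``(1, 3, 3)``
        applies a per-frame 3x3 spatial median with no temporal mixing.
    boundary_mode
        Edge-handling rule (scipy naming): ``reflect`` (default; edge
        sample repeated), ``mirror``, ``nearest``, ``wrap`` or ``constant``.
    """

    kernel: tuple[int, int, int] = (1, 3, 3)
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        if len(self.kernel) != 3:
            raise ValueError("kernel must have three lengths, one per (t, y, x) axis")
        for k in self.kernel:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"kernel lengths must be odd and >= 1; got {self.kernel}")
        if self.boundary_mode not in _PAD_MODE:
            raise ValueError(
                f"unknown boundary_mode {self.boundary_mode!r}; "
                f"choose from {sorted(_PAD_MODE)}"
            )


def _check_kernel_fits(stack: ImageStack, params: FilterParams) -> None:
    for k, dim, name in zip(params.kernel, stack.shape, ("t", "y", "x")):
        if k > dim:
            raise ValueError(
                f"kernel length {k} exceeds stack extent {dim} along axis {name}"
            )


def median_filter_stack(stack: ImageStack, params: FilterParams | None = None) -> ImageStack:
    """Apply the 3-D median filter; returns a new stack with ``is_filtered=True``.

    The output keeps the input's shape and dtype (the median of integers is
    an integer) and the input stack is left untouched.  With the default
    ``(1, 3, 3)`` kernel no information crosses frames.
    """
    params = params or FilterParams()
    _check_kernel_fits(stack, params)
    filtered = ndimage.median_filter(
        stack.data, size=params.kernel, mode=params.boundary_mode
    )
    out = replace(stack, data=filtered)
    out.is_filtered = True
    return out


def median_filter_oracle(stack: ImageStack, params: FilterParams | None = None) -> ImageStack:
    """Brute-force reference median filter: explicit per-pixel neighborhood sort.

    Pads the tensor according to the boundary rule, then for every voxel
    collects the full ``kt*ky*kx`` window, sorts it, and takes the middle
    element.  Intended for small stacks only (it is O(T*H*W*k^3 log k));
    serves as the independent equivalence oracle for
    :func:`median_filter_stack`.
    """
    params = params or FilterParams()
    _check_kernel_fits(stack, params)
    kt, ky, kx = params.kernel
    rt, ry, rx = kt // 2, ky // 2, kx // 2
    pad_mode = _PAD_MODE[params.boundary_mode]
    kwargs = {"constant_values": 0} if pad_mode == "constant" else {}
    padded = np.pad(stack.data, ((rt, rt), (ry, ry), (rx, rx)), mode=pad_mode, **kwargs)

    out = np.empty_like(stack.data)
    T, H, W = stack.shape
    mid = (kt * ky * kx) // 2
    for t in range(T):
        for y in range(H):
            for x in range(W):
                window = padded[t : t + kt, y : y + ky, x : x + kx]
                out[t, y, x] = np.sort(window, axis=None)[mid]
    result = replace(stack, data=out)
    result.is_filtered = True
    return result
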