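"""Ground-truthed synthetic blinking-movie generator.

The detector exploits one temporal signature: a pixel whose intensity
jumps and falls (or falls and jumps) across consecutive frames because the
emitter under it switched between emissive (ON) and dark (OFF) states.
The simulator reproduces exactly that signature with the minimal
photophysical model that has it:

* emitters are point sources at random subpixel positions, kept apart by a
  minimum center separation so each occupies its own patch of the field;
* each emitter's ON/OFF trace is an independent two-state Markov chain
  (telegraph process) with per-frame switching probabilities ``p_on``
  (OFF->ON) and ``p_off`` (ON->OFF); the stationary ON fraction is
  ``p_on / (p_on + p_off)``;
* an ON emitter deposits a 2-D Gaussian point-spread function of standard
  deviation ``psf_sigma`` pixels and peak ``amplitude`` ADU, sampled at
  pixel centers, on a flat ``background``;
* optional Poisson shot noise on the noiseless image, then additive
  Gaussian read noise, then clipping at zero and casting to the camera
  dtype (saturation at the dtype maximum is applied and logged).

Everything is driven by one seeded generator, so an identical
configuration reproduces the movie and its ground truth bit for bit.

The dose-response helper :func:`concentration_for_emitters` maps emitter
number to an analyte concentration assuming the bound-emitter density
grows linearly with log10(concentration) — the saturating wide-dynamic-
range binding behavior that makes single-molecule counts calibrate
linearly on a log-concentration axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .stack import ImageStack

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Could not place all emitters with the required minimum separation."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic movie.

    Defaults describe a bright, well-separated field: 50 emitters of peak
    amplitude 200 ADU over a 10 ADU background with 2 ADU read noise and
    shot noise on, blinking with ``p_on=0.2`` / ``p_off=0.5`` over 60
    frames of 256x256 pixels.
    """

    n_frames: int = 60
    height: int = 256
    width: int = 256
    pixel_size: float = 0.1          # um per pixel
    n_emitters: int = 50
    psf_sigma: float = 1.5           # pixels; 0 => all amplitude in one pixel
    amplitude: float = 200.0         # ADU at the peak when ON
    background: float = 10.0         # ADU
    p_on: float = 0.2                # per-frame OFF -> ON probability
    p_off: float = 0.5               # per-frame ON -> OFF probability
    initial_on_prob: float | None = None   # None => stationary p_on/(p_on+p_off)
    shot_noise: bool = True
    read_noise_sd: float = 2.0       # ADU, additive Gaussian
    seed: int = 0
    dtype: str = "uint16"
    enforce_separation: bool = True
    min_separation: float | None = None    # None => 4*psf_sigma + 2 pixels
    exposure_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_on", "p_off"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {p}")
        if self.initial_on_prob is not None and not 0.0 <= self.initial_on_prob <= 1.0:
            raise ValueError(f"initial_on_prob must be in [0, 1]")
        for name in ("amplitude", "background", "read_noise_sd", "psf_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 1 or self.height < 1 or self.width < 1:
            raise ValueError("n_frames, height and width must all be >= 1")
        if self.n_emitters < 0:
            raise ValueError("n_emitters must be >= 0")

    @property
    def separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 4.0 * self.psf_sigma + 2.0

    @property
    def stationary_on(self) -> float:
        if self.p_on + self.p_off == 0:
            return float(self.initial_on_prob or 0.0)
        return self.p_on / (self.p_on + self.p_off)


@dataclass
class GroundTruth:
    """Emitter positions and per-frame ON/OFF states for one movie."""

    positions: np.ndarray      # (n, 2) float (y, x) subpixel centers
    states: np.ndarray         # (n, T) bool, True = ON
    center_pixels: np.ndarray  # (n, 2) int rounded centers
    field_shape: tuple[int, int] = (0, 0)

    def blinked(self) -> np.ndarray:
        """Per-emitter flag: at least one ON<->OFF transition in the movie."""
        if self.states.shape[1] < 2:
            return np.zeros(self.states.shape[0], dtype=bool)
        return np.any(self.states[:, 1:] != self.states[:, :-1], axis=1)


@dataclass
class DetectionMetrics:
    """Recall over blinking emitters and false-positive pixel rate."""

    recall: float
    false_positive_rate: float
    n_blinking: int
    n_recovered: int
    n_detected_pixels: int
    n_false_pixels: int


def simulate_states(
    n_emitters: int,
    n_frames: int,
    p_on: float,
    p_off: float,
    initial_on_prob: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Independent two-state Markov (telegraph) ON/OFF traces.

    Returns a boolean matrix of shape ``(n_emitters, n_frames)``.  Each
    frame transition draws OFF->ON with probability ``p_on`` and ON->OFF
    with ``p_off``; the first frame is ON with ``initial_on_prob``
    (defaulting to the stationary probability ``p_on / (p_on + p_off)``).
    """
    if not (0.0 <= p_on <= 1.0 and 0.0 <= p_off <= 1.0):
        raise ValueError(f"probabilities must be in [0, 1]; got p_on={p_on}, p_off={p_off}")
    if initial_on_prob is None:
        initial_on_prob = p_on / (p_on + p_off) if (p_on + p_off) > 0 else 0.0
    if not 0.0 <= initial_on_prob <= 1.0:
        raise ValueError(f"initial_on_prob must be in [0, 1]; got {initial_on_prob}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    states = np.zeros((n_emitters, n_frames), dtype=bool)
    if n_frames == 0 or n_emitters == 0:
        return states
    states[:, 0] = rng.random(n_emitters) < initial_on_prob
    for t in range(1, n_frames):
        u = rng.random(n_emitters)
        on = states[:, t - 1]
        states[:, t] = np.where(on, u >= p_off, u < p_on)
    return states


def _place_emitters(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random subpixel positions, dart-throwing the separation rule."""
    n = config.n_emitters
    positions = np.empty((n, 2), dtype=float)
    if n == 0:
        return positions
    if not config.enforce_separation:
        positions[:, 0] = rng.uniform(0, config.height - 1, size=n)
        positions[:, 1] = rng.uniform(0, config.width - 1, size=n)
        return positions

    min_sep2 = config.separation**2
    budget = max(10_000, 500 * n)
    placed = 0
    for _ in range(budget):
        cand = np.array(
            [rng.uniform(0, config.height - 1), rng.uniform(0, config.width - 1)]
        )
        if placed == 0 or np.all(
            np.sum((positions[:placed] - cand) ** 2, axis=1) >= min_sep2
        ):
            positions[placed] = cand
            placed += 1
            if placed == n:
                return positions
    raise SeparationError(
        f"placed only {placed}/{n} emitters at separation >= "
        f"{config.separation:.2f} px within {budget} attempts"
    )


def render_movie(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a blinking movie and its ground truth from one seeded RNG.

    The noiseless frame is ``background + sum over ON emitters of
    amplitude * exp(-r^2 / (2 psf_sigma^2))`` sampled at pixel centers
    (``psf_sigma=0`` deposits the full amplitude in the rounded center
    pixel).  Poisson shot noise, Gaussian read noise, clipping at zero and
    dtype casting follow, in that order.
    """
    rng = np.random.default_rng(config.seed)
    T, H, W = config.n_frames, config.height, config.width
    positions = _place_emitters(config, rng)
    states = simulate_states(
        config.n_emitters, T, config.p_on, config.p_off,
        config.initial_on_prob, seed=rng,
    )
    center_pixels = np.round(positions).astype(int) if len(positions) else positions.astype(int)

    movie = np.full((T, H, W), float(config.background), dtype=np.float64)
    sigma = config.psf_sigma
    for i in range(config.n_emitters):
        cy, cx = positions[i]
        if sigma == 0.0:
            footprint = np.array([[config.amplitude]])
            y0, y1 = center_pixels[i, 0], center_pixels[i, 0] + 1
            x0, x1 = center_pixels[i, 1], center_pixels[i, 1] + 1
        else:
            r = int(np.ceil(4 * sigma)) + 1
            y0 = max(0, int(np.floor(cy)) - r)
            y1 = min(H, int(np.floor(cy)) + r + 1)
            x0 = max(0, int(np.floor(cx)) - r)
            x1 = min(W, int(np.floor(cx)) + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            footprint = config.amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
            )
        if y0 >= y1 or x0 >= x1:
            continue
        on_frames = np.nonzero(states[i])[0]
        for t in on_frames:
            movie[t, y0:y1, x0:x1] += footprint

    if config.shot_noise:
        movie = rng.poisson(movie).astype(np.float64)
    if config.read_noise_sd > 0:
        movie += rng.normal(0.0, config.read_noise_sd, size=movie.shape)
    np.clip(movie, 0.0, None, out=movie)

    dtype = np.dtype(config.dtype)
    if np.issubdtype(dtype, np.integer):
        max_val = np.iinfo(dtype).max
        n_sat = int(np.count_nonzero(movie > max_val))
        if n_sat:
            logger.warning("%d pixel samples saturated at %s max %d", n_sat, dtype, max_val)
            np.clip(movie, None, max_val, out=movie)
        movie = np.round(movie)
    data = movie.astype(dtype)

    stack = ImageStack(
        data, pixel_size=config.pixel_size, exposure_s=config.exposure_s,
        is_filtered=False,
    )
    truth = GroundTruth(
        positions=positions, states=states, center_pixels=center_pixels,
        field_shape=(H, W),
    )
    return stack, truth


def concentration_for_emitters(
    n_emitters: int | float,
    emitters_per_decade: float = 90.0,
    ref_concentration: float = 1.0,
) -> float:
    """Analyte concentration (pg/mL) whose bound-emitter number is ``n_emitters``.

    Models the surface density of captured, labeled molecules as growing
    linearly with log10 of the bulk concentration (saturating binding over
    a wide dynamic range): ``c = ref * 10**(n / emitters_per_decade)``.
    The inverse of the calibration relationship the counting pipeline fits.
    """
    if emitters_per_decade <= 0:
        raise ValueError("emitters_per_decade must be > 0")
    return float(ref_concentration * 10.0 ** (float(n_emitters) / emitters_per_decade))


def evaluate_detection(result, truth: GroundTruth, match_radius: float = 1.0) -> DetectionMetrics:
    """Score a detection mask against simulator ground truth.

    Recall is the fraction of *blinking* emitters (those with at least one
    ON<->OFF transition within the movie) whose rounded center pixel lies
    within ``match_radius`` (Euclidean, pixels) of some detected pixel.
    The false-positive rate is the fraction of all field pixels that were
    detected farther than ``match_radius`` from every emitter center.
    """
    mask = np.asarray(result.mask)
    if truth.field_shape != (0, 0) and mask.shape != tuple(truth.field_shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match simulated field "
            f"{tuple(truth.field_shape)}"
        )
    detected = np.argwhere(mask)  # (k, 2) (y, x)
    n_pixels = mask.size
    blinking = truth.blinked()
    n_blinking = int(blinking.sum())

    if len(detected) == 0:
        return DetectionMetrics(
            recall=0.0, false_positive_rate=0.0, n_blinking=n_blinking,
            n_recovered=0, n_detected_pixels=0, n_false_pixels=0,
        )

    centers = truth.center_pixels.reshape(-1, 2).astype(float)
    if len(centers) == 0:
        n_false = len(detected)
        return DetectionMetrics(
            recall=0.0 if n_blinking else float("nan"),
            false_positive_rate=n_false / n_pixels,
            n_blinking=n_blinking, n_recovered=0,
            n_detected_pixels=len(detected), n_false_pixels=n_false,
        )

    # pairwise squared distances detected-pixel x emitter-center
    d2 = (
        (detected[:, None, :].astype(float) - centers[None, :, :]) ** 2
    ).sum(axis=2)
    r2 = match_radius**2
    near = d2 <= r2

    recovered = near[:, blinking].any(axis=0) if n_blinking else np.zeros(0, dtype=bool)
    n_recovered = int(recovered.sum())
    recall = n_recovered / n_blinking if n_blinking else float("nan")

    n_false = int((~near.any(axis=1)).sum())
    return DetectionMetrics(
        recall=recall,
        false_positive_rate=n_false / n_pixels,
        n_blinking=n_blinking,
        n_recovered=n_recovered,
        n_detected_pixels=int(len(detected)),
        n_false_pixels=n_false,
    )
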