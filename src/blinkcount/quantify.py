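"""Analysis layer: threshold screening, grid density, log-concentration calibration.

Three pieces sit on top of the detector:

* **Threshold sweep** — run the filter-then-detect pipeline over a grid of
  thresholds and a set of movies at known analyte concentrations.  Counts
  are non-increasing in tau for every movie (raising tau can only remove
  detections), which the sweep table asserts on construction.
* **Threshold selection** — the operating threshold should capture true
  transients while rejecting background, which operationally means the
  counts must rise monotonically with concentration.  Too low a tau
  overcounts noise (flattening the low end); too high a tau underdetects.
  The selector scores each tau lexicographically: (a) Spearman rank
  correlation between concentration and count (a strictly increasing
  response scores 1), then (b) R-squared of the log-linear calibration fit,
  then (c) the smallest count on the lowest-concentration (blank-most)
  movie.
* **Calibration** — ordinary least squares of the response against
  ``x = log10(concentration in pg/mL)``, the standard dose-response axis
  for assays spanning several decades; plus the 36 um^2 grid-density
  convention used by manual counting, and a side-by-side manual-vs-auto
  comparison report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detect import DetectionResult, DetectorParams, detect_stack
from .filtering import FilterParams, median_filter_stack
from .stack import ImageStack, load_stack

X_DEFINITION = "x = log10(concentration in pg/mL)"


@dataclass
class MovieRecord:
    """One movie in a concentration series: label, concentration (pg/mL), data."""

    label: str
    concentration: float
    stack_ref: ImageStack | str | Path

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError(
                f"concentration must be > 0 pg/mL (log10 must exist); "
                f"got {self.concentration}"
            )

    def stack(self) -> ImageStack:
        if isinstance(self.stack_ref, ImageStack):
            return self.stack_ref
        return load_stack(self.stack_ref)


@dataclass
class SweepResult:
    """Counts N indexed by (movie, tau); rows are movies, columns thresholds."""

    taus: list[float]
    counts: pd.DataFrame
    provenance: FilterParams = field(default_factory=FilterParams)

    def __post_init__(self) -> None:
        cols = list(self.counts.columns)
        if cols != sorted(cols):
            raise ValueError("sweep columns (taus) must be in increasing order")
        arr = self.counts.to_numpy()
        if arr.shape[1] > 1 and np.any(np.diff(arr, axis=1) > 0):
            bad = self.counts.index[np.any(np.diff(arr, axis=1) > 0, axis=1)]
            raise ValueError(
                f"counts must be non-increasing in tau; violated for {list(bad)}"
            )


@dataclass(frozen=True)
class GridSpec:
    """Square-grid convention for areal density: 36 um^2 squares by default."""

    pixel_size: float
    square_area: float = 36.0

    @property
    def side_pixels(self) -> int:
        side = round(math.sqrt(self.square_area) / self.pixel_size)
        if side < 1:
            raise ValueError(
                f"grid square side rounds to < 1 pixel "
                f"(area {self.square_area} um^2 at {self.pixel_size} um/px)"
            )
        return side


@dataclass
class DensityResult:
    """Per-grid counts and densities (counts per um^2) plus their mean."""

    per_grid_counts: np.ndarray   # (n_gy, n_gx) ints, row-major grid layout
    densities: np.ndarray         # same shape, counts / square_area
    mean_density: float
    n_grids: int
    selected_grids: list[int] | None = None  # flat row-major indices


@dataclass
class CalibrationFit:
    """OLS fit of response on x = log10(concentration in pg/mL).

    ``r_squared`` is None (with ``r_squared_defined=False``) when the
    responses are constant (SS_tot = 0); it is never silently reported as
    0 or 1 in that case.
    """

    slope: float
    intercept: float
    r_squared: float | None
    r_squared_defined: bool
    n_points: int
    x_definition: str = X_DEFINITION

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "r_squared_defined": self.r_squared_defined,
            "n_points": self.n_points,
            "x_definition": self.x_definition,
        }


def sweep_thresholds(
    movies: Sequence[MovieRecord],
    taus: Sequence[float],
    filter_params: FilterParams | None = None,
) -> SweepResult:
    """Run the pipeline for every (movie, tau) pair.

    Each movie is median-filtered once and the filtered stack is reused
    across all thresholds — detection itself is cheap, filtering is not.
    """
    if len(taus) == 0:
        raise ValueError("taus must be non-empty")
    filter_params = filter_params or FilterParams()
    taus_sorted = sorted(float(t) for t in taus)

    rows = {}
    for movie in movies:
        filtered = median_filter_stack(movie.stack(), filter_params)
        rows[movie.label] = [
            detect_stack(filtered, DetectorParams(tau=t)).count for t in taus_sorted
        ]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=taus_sorted)
    counts.index.name = "movie"
    counts.columns.name = "tau"
    return SweepResult(taus=taus_sorted, counts=counts, provenance=filter_params)


def select_threshold(
    sweep: SweepResult,
    concentrations: Mapping[str, float],
) -> tuple[float, pd.DataFrame]:
    """Pick the operating threshold tau* from a sweep table.

    Scores every tau lexicographically by (a) Spearman rank correlation of
    counts with concentration, (b) R-squared of the log-linear fit of count
    on log10(concentration), (c) negated count on the lowest-concentration
    movie (fewer blank detections is better).  Returns ``(tau_star,
    diagnostics)`` where the diagnostics table lists all three scores per
    tau plus a ``monotone`` flag; its ``attrs["warning"]`` is True when no
    tau achieves a strictly increasing concentration response.

    ``concentrations`` maps movie labels (the sweep's row index) to pg/mL.
    """
    labels = list(sweep.counts.index)
    missing = [lab for lab in labels if lab not in concentrations]
    if missing:
        raise ValueError(f"no concentration given for movies: {missing}")
    conc = np.array([concentrations[lab] for lab in labels], dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct concentrations to rank thresholds")
    order = np.argsort(conc)
    blank_idx = order[0]

    records = []
    for tau in sweep.taus:
        counts = sweep.counts[tau].to_numpy(dtype=float)
        if np.ptp(counts) == 0:
            rho = float("-inf")  # flat response carries no concentration signal
        else:
            rho = float(stats.spearmanr(conc, counts).statistic)
            if math.isnan(rho):
                rho = float("-inf")
        fit = fit_log_linear(list(zip(conc, counts)))
        r2 = fit.r_squared if fit.r_squared_defined else float("-inf")
        blank = float(counts[blank_idx])
        monotone = bool(np.all(np.diff(counts[order]) > 0))
        records.append(
            {"tau": tau, "spearman": rho, "r_squared": r2, "blank_count": blank,
             "monotone": monotone}
        )
    diag = pd.DataFrame.from_records(records).set_index("tau")

    best_tau, best_score = None, None
    for rec in records:
        score = (rec["spearman"], rec["r_squared"], -rec["blank_count"])
        if best_score is None or score > best_score:
            best_tau, best_score = rec["tau"], score
    diag.attrs["warning"] = not any(r["monotone"] for r in records)
    return float(best_tau), diag


def grid_density(
    mask: DetectionResult | np.ndarray,
    spec: GridSpec,
    selected_grids: Sequence[int] | None = None,
    n_random: int | None = None,
    seed: int | None = None,
) -> DensityResult:
    """Partition a detection mask into grid squares and compute areal density.

    The field is tiled with non-overlapping squares of side
    ``round(sqrt(square_area) / pixel_size)`` pixels starting at the
    top-left origin; partial edge squares are discarded.  Each density is
    the square's true-pixel count divided by the *nominal* square area
    (even when side rounding makes the realized pixel area differ
    slightly).  The mean uses all grids, an explicit ``selected_grids``
    list of flat row-major indices, or ``n_random`` squares drawn with the
    given seed — mirroring the manual protocol of averaging a few
    independently chosen grid regions.
    """
    grid = mask.mask if isinstance(mask, DetectionResult) else np.asarray(mask)
    if grid.ndim != 2:
        raise ValueError("mask must be 2-D")
    side = spec.side_pixels
    H, W = grid.shape
    if side > H or side > W:
        raise ValueError(
            f"grid square side {side} px exceeds mask dimensions {H}x{W}"
        )
    n_gy, n_gx = H // side, W // side
    counts = (
        grid[: n_gy * side, : n_gx * side]
        .reshape(n_gy, side, n_gx, side)
        .sum(axis=(1, 3))
        .astype(int)
    )
    densities = counts / spec.square_area
    n_grids = n_gy * n_gx

    if selected_grids is not None and n_random is not None:
        raise ValueError("give selected_grids or n_random, not both")
    sel: list[int] | None = None
    if selected_grids is not None:
        sel = [int(i) for i in selected_grids]
        if any(i < 0 or i >= n_grids for i in sel):
            raise ValueError(f"grid index out of range 0..{n_grids - 1}")
    elif n_random is not None:
        if n_random > n_grids:
            raise ValueError(f"cannot select {n_random} of {n_grids} grids")
        rng = np.random.default_rng(seed)
        sel = sorted(int(i) for i in rng.choice(n_grids, size=n_random, replace=False))

    flat = densities.ravel()
    mean = float(flat[sel].mean()) if sel is not None else float(flat.mean())
    return DensityResult(
        per_grid_counts=counts,
        densities=densities,
        mean_density=mean,
        n_grids=n_grids,
        selected_grids=sel,
    )


def fit_log_linear(points: Sequence[tuple[float, float]]) -> CalibrationFit:
    """OLS of response y on x = log10(concentration pg/mL).

    Closed-form normal equations; the intercept is the predicted response
    at 1 pg/mL (x = 0).  R-squared = 1 - SS_res/SS_tot, flagged undefined
    when the responses are constant (SS_tot = 0).
    """
    if len(points) < 2:
        raise ValueError(f"need >= 2 points for a fit; got {len(points)}")
    conc = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive (pg/mL)")
    x = np.log10(conc)
    if np.ptp(x) == 0:
        raise ValueError("all concentrations identical: slope undefined")

    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0.0:
        return CalibrationFit(
            slope=float(slope), intercept=float(intercept),
            r_squared=None, r_squared_defined=False, n_points=len(points),
        )
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationFit(
        slope=float(slope), intercept=float(intercept),
        r_squared=r2, r_squared_defined=True, n_points=len(points),
    )


@dataclass
class MethodComparison:
    """Side-by-side calibration of manual density vs automated counts."""

    manual_fit: CalibrationFit
    auto_fit: CalibrationFit
    table: pd.DataFrame  # columns: concentration, manual, auto


def compare_methods(
    manual: Mapping[float, float],
    auto: Mapping[float, float],
) -> MethodComparison:
    """Fit both counting methods against log10(concentration) and tabulate.

    ``manual`` maps concentration (pg/mL) to mean areal density
    (counts/um^2); ``auto`` maps the same concentrations to automated
    counts (raw N or a density — the two series need not share a scale,
    only a concentration set).
    """
    if set(manual) != set(auto):
        raise ValueError(
            f"concentration sets differ: manual {sorted(manual)} vs auto {sorted(auto)}"
        )
    concs = sorted(manual)
    manual_fit = fit_log_linear([(c, manual[c]) for c in concs])
    auto_fit = fit_log_linear([(c, auto[c]) for c in concs])
    table = pd.DataFrame(
        {
            "concentration_pg_per_ml": concs,
            "manual": [manual[c] for c in concs],
            "auto": [auto[c] for c in concs],
        }
    )
    return MethodComparison(manual_fit=manual_fit, auto_fit=auto_fit, table=table)
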