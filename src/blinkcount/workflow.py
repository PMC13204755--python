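"""End-to-end orchestration: manifest -> sweep -> threshold -> calibration.

A run manifest names the movies (path, label, concentration), the filter
settings, the threshold grid and an output directory.  ``run_end_to_end``
executes filter -> detect across the full (movie, tau) grid, picks the
operating threshold, fits the log-concentration calibration at that
threshold, and writes the sweep table, fit record, per-movie detection
masks and a human-readable summary.

Reproducibility contract: every output is stamped with the package
version, a SHA-256 hash of the canonical manifest, and the parameters
used; nothing in the outputs depends on wall-clock time, so a rerun with
the same manifest and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile
import yaml

from . import __version__
from .filtering import FilterParams
from .quantify import (
    CalibrationFit,
    MovieRecord,
    SweepResult,
    fit_log_linear,
    select_threshold,
    sweep_thresholds,
)
from .stack import load_stack


class ManifestError(ValueError):
    """Manifest validation failed; the message lists every problem at once."""


def parse_taus(spec: str | Sequence[float]) -> list[float]:
    """Threshold grid from an explicit list or a ``start:stop:step`` range.

    The range is inclusive of ``stop`` when the step lands on it exactly.
    """
    if isinstance(spec, str):
        parts = spec.split(":")
        if len(parts) != 3:
            raise ManifestError(f"tau range must be start:stop:step; got {spec!r}")
        start, stop, step = (float(p) for p in parts)
        if step <= 0 or stop < start:
            raise ManifestError(f"invalid tau range {spec!r}")
        values = list(np.arange(start, stop + step / 2.0, step))
        return [float(v) for v in values]
    return [float(t) for t in spec]


@dataclass
class MovieEntry:
    path: str
    label: str
    concentration: float
    pixel_size: float | None = None
    exposure_s: float | None = None


@dataclass
class RunManifest:
    """Everything one reproducible run needs, loadable from YAML."""

    movies: list[MovieEntry]
    taus: list[float]
    output_dir: str
    filter: FilterParams = field(default_factory=FilterParams)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunManifest":
        movies = [
            MovieEntry(
                path=str(m["path"]),
                label=str(m.get("label", Path(str(m["path"])).stem)),
                concentration=float(m.get("concentration_pg_per_ml", m.get("concentration", 0))),
                pixel_size=m.get("pixel_size"),
                exposure_s=m.get("exposure_s"),
            )
            for m in d.get("movies", [])
        ]
        fd = d.get("filter", {})
        filt = FilterParams(
            kernel=tuple(fd.get("kernel", (1, 3, 3))),
            boundary_mode=fd.get("boundary_mode", "reflect"),
        )
        return cls(
            movies=movies,
            taus=parse_taus(d.get("taus", [])),
            output_dir=str(d.get("output_dir", ".")),
            filter=filt,
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        """Raise ManifestError listing *all* problems, not just the first."""
        problems: list[str] = []
        if not self.movies:
            problems.append("movies: list is empty")
        labels = [m.label for m in self.movies]
        if len(set(labels)) != len(labels):
            problems.append("movies: labels are not unique")
        for m in self.movies:
            if not Path(m.path).exists():
                problems.append(f"movies[{m.label}].path: no such file {m.path}")
            if not m.concentration > 0:
                problems.append(
                    f"movies[{m.label}].concentration: must be > 0 pg/mL, "
                    f"got {m.concentration}"
                )
        if not self.taus:
            problems.append("taus: list is empty (required for sweep runs)")
        if problems:
            raise ManifestError("; ".join(problems))

    def canonical_dict(self) -> dict[str, Any]:
        return {
            "movies": [
                {
                    "path": m.path,
                    "label": m.label,
                    "concentration_pg_per_ml": m.concentration,
                    "pixel_size": m.pixel_size,
                    "exposure_s": m.exposure_s,
                }
                for m in self.movies
            ],
            "filter": {
                "kernel": list(self.filter.kernel),
                "boundary_mode": self.filter.boundary_mode,
            },
            "taus": self.taus,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    def hash(self) -> str:
        canon = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


class RunLog:
    """Append-only, machine-parseable stage log (JSON lines).

    Events are ordered by a sequence number rather than wall-clock time so
    logs from identical runs are themselves identical.
    """

    def __init__(self) -> None:
        self.events: list[dict[str, Any]] = []

    def log(self, stage: str, event: str, **fields: Any) -> None:
        self.events.append({"seq": len(self.events), "stage": stage,
                            "event": event, **fields})

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev, sort_keys=True) + "\n")


@dataclass
class RunReport:
    """Results and output paths of one end-to-end run."""

    sweep: SweepResult
    tau_star: float
    fit: CalibrationFit
    counts_at_tau_star: dict[str, int]
    manifest_hash: str
    output_dir: Path
    warning: bool
    log: RunLog


def _stamp(manifest: RunManifest) -> dict[str, Any]:
    return {
        "software": "blinkcount",
        "version": __version__,
        "manifest_hash": manifest.hash(),
        "parameters": manifest.canonical_dict(),
        "frame_indexing": "1-based",
        "coordinates": "(y, x) pixels, origin top-left",
    }


def run_end_to_end(manifest: RunManifest) -> RunReport:
    """Full pipeline: sweep thresholds, select tau*, calibrate, write outputs.

    Writes into ``manifest.output_dir``: ``sweep.csv`` (counts per movie
    and tau, stamped header comments), ``fit.json`` (tau*, calibration fit
    and per-movie counts), ``mask_<label>.tif`` (8-bit 0/255 detection
    mask at tau* per movie), ``summary.txt`` and ``run_log.jsonl``.
    """
    manifest.validate()
    log = RunLog()
    stamp = _stamp(manifest)
    log.log("run", "start", manifest_hash=stamp["manifest_hash"], version=__version__)

    records = []
    for m in manifest.movies:
        stack = load_stack(m.path, pixel_size=m.pixel_size, exposure_s=m.exposure_s)
        records.append(MovieRecord(label=m.label, concentration=m.concentration,
                                   stack_ref=stack))
        log.log("load", "loaded", label=m.label, n_frames=stack.n_frames,
                height=stack.height, width=stack.width)

    sweep = sweep_thresholds(records, manifest.taus, manifest.filter)
    log.log("sweep", "done", n_movies=len(records), n_taus=len(sweep.taus),
            kernel=list(manifest.filter.kernel))

    concentrations = {m.label: m.concentration for m in manifest.movies}
    tau_star, diag = select_threshold(sweep, concentrations)
    warning = bool(diag.attrs.get("warning", False))
    log.log("select", "done", tau_star=tau_star, warning=warning)

    counts_star = {lab: int(sweep.counts.loc[lab, tau_star]) for lab in sweep.counts.index}
    fit = fit_log_linear(
        [(concentrations[lab], counts_star[lab]) for lab in sweep.counts.index]
    )
    log.log("calibrate", "done", tau=tau_star, slope=fit.slope,
            intercept=fit.intercept, r_squared=fit.r_squared)

    out = Path(manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    sweep_path = out / "sweep.csv"
    with open(sweep_path, "w") as fh:
        for key in ("software", "version", "manifest_hash"):
            fh.write(f"# {key}: {stamp[key]}\n")
        fh.write(f"# frame_indexing: {stamp['frame_indexing']}\n")
        fh.write(f"# coordinates: {stamp['coordinates']}\n")
        long = sweep.counts.reset_index().melt(
            id_vars="movie", var_name="tau", value_name="count"
        )
        long["concentration_pg_per_ml"] = long["movie"].map(concentrations)
        long = long[["movie", "concentration_pg_per_ml", "tau", "count"]]
        long.to_csv(fh, index=False)

    fit_path = out / "fit.json"
    with open(fit_path, "w") as fh:
        json.dump(
            {
                **stamp,
                "tau_star": tau_star,
                "selection_warning": warning,
                "fit": fit.as_dict(),
                "counts_at_tau_star": counts_star,
                "concentrations_pg_per_ml": concentrations,
            },
            fh, sort_keys=True, indent=2,
        )
        fh.write("\n")

    from .detect import DetectorParams, run_pipeline  # local import: avoid cycle

    for rec in records:
        result = run_pipeline(rec.stack(), manifest.filter, DetectorParams(tau=tau_star))
        mask_img = (result.mask.astype(np.uint8)) * 255
        tifffile.imwrite(out / f"mask_{rec.label}.tif", mask_img,
                         photometric="minisblack")
        log.log("mask", "written", label=rec.label, count=result.count)

    summary_path = out / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write("blinkcount end-to-end run\n")
        fh.write(f"version: {__version__}\n")
        fh.write(f"manifest_hash: {stamp['manifest_hash']}\n")
        fh.write(f"filter kernel: {manifest.filter.kernel} "
                 f"boundary: {manifest.filter.boundary_mode}\n")
        fh.write(f"thresholds screened: {sweep.taus}\n")
        fh.write(f"selected tau*: {tau_star}"
                 + ("  (WARNING: no strictly monotone threshold)\n" if warning else "\n"))
        fh.write(f"calibration ({fit.x_definition}):\n")
        fh.write(f"  slope={fit.slope:.6g} intercept={fit.intercept:.6g} "
                 f"R^2={'undefined' if not fit.r_squared_defined else format(fit.r_squared, '.6g')}\n")
        fh.write("counts at tau* (frame indices 1-based):\n")
        for lab in sweep.counts.index:
            fh.write(f"  {lab}: concentration={concentrations[lab]} pg/mL "
                     f"N={counts_star[lab]}\n")

    log.log("run", "end", outputs=[p.name for p in
                                   (sweep_path, fit_path, summary_path)])
    log.to_jsonl(out / "run_log.jsonl")

    return RunReport(
        sweep=sweep, tau_star=tau_star, fit=fit, counts_at_tau_star=counts_star,
        manifest_hash=stamp["manifest_hash"], output_dir=out, warning=warning,
        log=log,
    )
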