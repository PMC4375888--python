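"""File formats, reports, and the pipeline driver.

Interchange formats are deliberately plain:

* traces — CSV with columns ``time_s, length_subunits`` and an optional
  ``phase`` ground-truth column;
* kymographs — 16-bit unsigned grayscale TIFF plus a JSON sidecar
  carrying ``pixel_size_um`` and ``frame_interval_s``;
* contours — CSV with ``x_um, y_um, filament_id``;
* density responses — CSV with
  ``density_per_um2, occupancy, v_mean, v_std, n``;
* reports — JSON with a schema version, the configuration echo, the
  global seed and SHA-256 hashes of every input, so any number in a
  report can be regenerated bit-exactly.

Lengths are stored in subunits in trace files (the native unit of the
simulators); conversion to microns always uses 370 subunits per micron.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import allosteric, kinetics, kymo, persistence, synthetic
from .config import PipelineConfig, derive_seed

logger = logging.getLogger("filakin")

SCHEMA_VERSION = "1"

__all__ = [
    "read_kymograph",
    "write_kymograph",
    "read_trace",
    "write_trace",
    "read_contours",
    "write_contours",
    "read_density_response",
    "write_density_response",
    "write_report",
    "validate_report",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# kymographs


def write_kymograph(kym: kymo.Kymograph, path, sidecar=None) -> None:
    """Write a kymograph as 16-bit unsigned TIFF + JSON calibration sidecar.

    Intensities are rounded and clipped into the uint16 range; pass
    integer-valued data for a lossless round trip.
    """
    path = Path(path)
    data = np.clip(np.round(kym.intensities), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"pixel_size_um": kym.pixel_size_um, "frame_interval_s": kym.frame_interval_s},
            sort_keys=True,
        )
    )


def read_kymograph(
    path,
    sidecar=None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> kymo.Kymograph:
    """Read a TIFF kymograph; calibration from the sidecar or arguments."""
    path = Path(path)
    try:
        data = tifffile.imread(path).astype(float)
    except Exception as exc:  # corrupted / not a TIFF
        raise ValueError(f"could not read kymograph TIFF {path}: {exc}") from exc
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]

    meta = {}
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    if px is None:
        raise ValueError("missing calibration: pixel_size_um (no sidecar value or argument)")
    if dt is None:
        raise ValueError("missing calibration: frame_interval_s (no sidecar value or argument)")
    return kymo.Kymograph(data, float(px), float(dt))


# ---------------------------------------------------------------------------
# traces / contours / density tables


def write_trace(trace: kymo.FilamentTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "length_subunits": trace.delta_length})
    if trace.phase is not None:
        df["phase"] = np.where(trace.phase, "active", "paused")
    df.to_csv(path, index=False)


def read_trace(path, end: str = "barbed") -> kymo.FilamentTrace:
    df = pd.read_csv(path)
    phase = None
    if "phase" in df.columns:
        phase = df["phase"].to_numpy() == "active"
    return kymo.FilamentTrace(
        df["time_s"].to_numpy(),
        df["length_subunits"].to_numpy(),
        end=end,
        phase=phase,
    )


def write_contours(contours, path) -> None:
    frames = []
    for i, c in enumerate(contours):
        frames.append(
            pd.DataFrame({"x_um": c.points[:, 0], "y_um": c.points[:, 1], "filament_id": i})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_contours(path) -> list[persistence.Contour]:
    df = pd.read_csv(path)
    return [
        persistence.Contour(g[["x_um", "y_um"]].to_numpy())
        for _, g in df.groupby("filament_id", sort=True)
    ]


def write_density_response(dr: allosteric.DensityResponse, path) -> None:
    dr.to_frame().to_csv(path, index=False)


def read_density_response(path) -> allosteric.DensityResponse:
    return allosteric.DensityResponse.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# reports


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(results: dict, path, config: dict | None = None, seed: int | None = None, inputs=None) -> dict:
    """Write a reproducibility report: schema version, config echo, seed, hashes.

    The report carries no timestamps, so identical config + seed produce
    byte-identical files.  Returns the report dict.
    """
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": config or {},
        "input_hashes": {str(p): _sha256(p) for p in (inputs or [])},
        "results": results,
    }
    validate_report(report)
    path = Path(path)
    try:
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return report


def _load_schema() -> dict:
    with resources.files("filakin").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "string": str,
    "integer": int,
    "null": type(None),
}


def validate_report(report: dict) -> None:
    """Check a report against the bundled JSON schema (required keys + types)."""
    schema = _load_schema()
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing required field '{key}'")
    for key, rule in schema["properties"].items():
        if key not in report:
            continue
        types = rule["type"]
        types = types if isinstance(types, list) else [types]
        if not isinstance(report[key], tuple(_TYPES[t] for t in types)):
            raise ValueError(f"report field '{key}' has wrong type")


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: PipelineConfig | dict, stages=None, inputs: dict | None = None, out=None) -> dict:
    """Run the analysis stages in order and emit one consolidated report.

    ``stages`` is a subset of ``["simulate", "render", "track",
    "kinetics", "fit_rates", "fit_mc", "persistence"]`` (default: the
    synthetic end-to-end chain simulate -> render -> track ->
    kinetics).  ``inputs`` may supply file paths (``kymograph``,
    ``trace``, ``contours``, ``density_response``, ``rates_table``) or
    in-memory objects; a stage reuses the previous stage's product when
    none is given.  Per-stage wall time is logged; a failing stage
    aborts with the stage named, preserving earlier results in the
    raised error's ``partial`` attribute.
    """
    if isinstance(config, dict):
        extra = {k: v for k, v in config.items() if k not in PipelineConfig.__dataclass_fields__}
        known = {k: v for k, v in config.items() if k in PipelineConfig.__dataclass_fields__ and k != "extra"}
        cfg = PipelineConfig(**known, extra=extra)
    else:
        cfg = config
    stages = list(stages) if stages is not None else ["simulate", "render", "track", "kinetics"]
    inputs = dict(inputs or {})
    results: dict = {}
    state: dict = {}
    files: list = []

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            err = RuntimeError(f"pipeline stage '{name}' failed: {exc}")
            err.partial = results  # type: ignore[attr-defined]
            raise err from exc
        logger.info("stage %s finished in %.3f s", name, time.perf_counter() - t0)

    def stage_simulate():
        kwargs = {"kon": cfg.kon0, "koff": cfg.koff, "seed": derive_seed(cfg.seed, "simulate")}
        kwargs.update(cfg.extra.get("growth", {}))
        gp = synthetic.GrowthParams(**kwargs)
        state["trace"] = synthetic.simulate_growth_trace(gp)
        results["simulate"] = {
            "n_samples": int(state["trace"].times.size),
            "final_delta_subunits": float(state["trace"].delta_length[-1]),
        }

    def stage_render():
        rp = synthetic.RenderParams(
            pixel_size_um=cfg.pixel_size_um,
            frame_interval_s=cfg.frame_interval_s,
            seed=derive_seed(cfg.seed, "render"),
            **cfg.extra.get("render", {}),
        )
        state["kymograph"] = synthetic.render_kymograph(state["trace"], rp)
        results["render"] = {
            "shape": list(state["kymograph"].intensities.shape),
        }

    def stage_track():
        if "kymograph" in inputs and "kymograph" not in state:
            obj = inputs["kymograph"]
            state["kymograph"] = obj if isinstance(obj, kymo.Kymograph) else read_kymograph(obj)
            if not isinstance(obj, kymo.Kymograph):
                files.append(obj)
        barbed, pointed = kymo.track_ends(state["kymograph"])
        state["barbed"], state["pointed"] = barbed, pointed
        results["track"] = {
            "gap_fraction_barbed": barbed.gap_fraction,
            "gap_fraction_pointed": pointed.gap_fraction,
        }

    def stage_kinetics():
        trace = state.get("barbed")
        if trace is None:
            obj = inputs.get("trace", state.get("trace"))
            if obj is None:
                raise ValueError("kinetics stage needs a trace input")
            trace = obj if isinstance(obj, kymo.FilamentTrace) else read_trace(obj)
            if not isinstance(obj, kymo.FilamentTrace):
                files.append(obj)
        v = kinetics.smooth_velocity(trace, window=cfg.smoothing_window)
        summary = kinetics.classify_phases(v, threshold=cfg.pause_threshold)
        pf = kinetics.pause_free_velocity(trace, threshold=cfg.pause_threshold, window=cfg.smoothing_window)
        results["kinetics"] = {
            "pause_free_velocity": pf.velocity,
            "sem": pf.sem,
            "n_runs": pf.n_runs,
            "pausing_probability": summary.pausing_probability,
        }

    def stage_fit_rates():
        obj = inputs["rates_table"]
        if isinstance(obj, (str, Path)):
            df = pd.read_csv(obj)
            files.append(obj)
            cols = [df["conc_uM"], df["E"], df.get("sem")]
            pts = list(zip(*[c for c in cols if c is not None]))
        else:
            pts = obj
        rates = kinetics.fit_rate_constants(pts)
        results["fit_rates"] = {
            "kon": rates.kon,
            "koff": rates.koff,
            "cc": rates.cc,
            "ci95_kon": list(rates.ci95_kon),
            "ci95_koff": list(rates.ci95_koff),
            "n_points": rates.n_points,
        }

    def stage_fit_mc():
        obj = inputs["density_response"]
        dr = obj if isinstance(obj, allosteric.DensityResponse) else read_density_response(obj)
        if not isinstance(obj, allosteric.DensityResponse):
            files.append(obj)
        mc_cfg = allosteric.MCConfig(
            kon0=cfg.kon0,
            koff=cfg.koff,
            lattice_size=cfg.lattice_size,
            seed=derive_seed(cfg.seed, "fit_mc"),
            **cfg.extra.get("mc", {}),
        )
        fit = allosteric.grid_fit(dr, mc_cfg, **cfg.extra.get("grid", {}))
        results["fit_mc"] = {
            "alpha": fit.alpha,
            "lc": fit.lc,
            "chi2_min": fit.chi2_min,
            "ci68_alpha": list(fit.ci68_alpha),
            "ci95_alpha": list(fit.ci95_alpha),
            "ci68_lc": list(fit.ci68_lc),
            "ci95_lc": list(fit.ci95_lc),
            "boundary_flag": fit.boundary,
        }

    def stage_persistence():
        obj = inputs["contours"]
        contours = obj if not isinstance(obj, (str, Path)) else read_contours(obj)
        if isinstance(obj, (str, Path)):
            files.append(obj)
        fit = persistence.estimate_lp(contours)
        results["persistence"] = {
            "lp_um": fit.lp,
            "s_max_um": fit.s_max,
            "n_filaments": fit.n_filaments,
            "capped": fit.capped,
        }

    dispatch = {
        "simulate": stage_simulate,
        "render": stage_render,
        "track": stage_track,
        "kinetics": stage_kinetics,
        "fit_rates": stage_fit_rates,
        "fit_mc": stage_fit_mc,
        "persistence": stage_persistence,
    }
    for name in stages:
        if name not in dispatch:
            raise ValueError(f"unknown stage '{name}'")
        run_stage(name, dispatch[name])

    config_echo = {k: getattr(cfg, k) for k in PipelineConfig.__dataclass_fields__ if k != "extra"}
    config_echo["extra"] = cfg.extra
    config_echo["stages"] = stages
    if out is not None:
        return write_report(results, out, config=config_echo, seed=cfg.seed, inputs=files)
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "config": config_echo,
        "input_hashes": {str(p): _sha256(p) for p in files},
        "results": results,
    }
    validate_report(report)
    return report
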