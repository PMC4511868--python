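"""Configuration-driven orchestration of the two study workflows.

``target_sr`` measures spatial resolution before and after multi-frame
super-resolution on a simulated step-edge marker (one edge per direction),
the metrology workflow run on a resolution target.

``aerosol_mcr_sr`` is the full chemical-imaging chain: acquire (or load) a
series of sub-pixel-shifted hyperspectral cubes, AsLS-correct every pixel
spectrum, factor the column-wise augmented multiset by MCR-ALS, refold the
concentration blocks into per-frame maps for every component, and solve
the super-resolution inverse problem component by component (one shared
PSF and upsampling factor — same optical system for all maps).

Every run emits a machine-readable JSON report carrying the metrics, the
full configuration, the seed and a config hash, sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baseline import BaselineParams, correct_cube
from .hyperdata import augment_multiset, refold_maps, save_cube, save_map
from .mcr import MCRALS
from .resolution import step_edge_resolution
from .superres import (PSFModel, SRConfig, ShiftedMapSeries,
                       choose_decimation, solve_super_resolution)
from .synthetic import (make_edge_target, make_mixture_scene,
                        raster_shift_grid, simulate_cube_series,
                        simulate_map_series)

__all__ = ["RunConfig", "run_workflow"]

log = logging.getLogger("hypersr")

_BLOCK_KEYS = {
    "simulate": {"n_components", "include_background", "baseline_scale",
                 "noise_sigma", "hr_shape", "hr_pixel_size", "n_side",
                 "step_um", "canvas", "edge_position", "axis_start",
                 "axis_stop", "axis_step"},
    "baseline": {"lam", "p", "max_iter", "tol", "enabled"},
    "mcr": {"n_components", "tol", "max_iter", "nonneg_mode", "alpha",
            "svd_threshold"},
    "sr": {"k", "lambda_reg", "alpha", "P", "beta", "n_iter", "tol",
           "psf_fwhm"},
    "resolution": {"n_profiles"},
}


@dataclass
class RunConfig:
    """Validated, declarative description of one workflow run."""

    workflow: str
    output_dir: str = "hypersr_run"
    seed: int = 0
    log_level: str = "INFO"
    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    mcr: dict = field(default_factory=dict)
    sr: dict = field(default_factory=dict)
    resolution: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.workflow not in ("target_sr", "aerosol_mcr_sr", "simulate"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        for block, allowed in _BLOCK_KEYS.items():
            extra = set(getattr(self, block)) - allowed
            if extra:
                raise ValueError(f"unknown keys in {block!r} block: {sorted(extra)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"inputs.{key}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path, overrides=None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        extra = set(raw) - set(cls.__dataclass_fields__)
        if extra:
            raise ValueError(f"{path}: unknown top-level keys {sorted(extra)}")
        if overrides:
            raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_workflow(config: RunConfig) -> dict:
    """Execute the configured workflow; returns (and writes) the run report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "workflow": config.workflow,
        "seed": config.seed,
        "config_hash": config.digest(),
        "version": __version__,
        "config": asdict(config),
        "artifacts": {},
        "metrics": {},
    }
    stage = "setup"
    try:
        if config.workflow == "target_sr":
            _target_workflow(config, out, report)
        elif config.workflow == "aerosol_mcr_sr":
            _aerosol_workflow(config, out, report)
        else:
            _simulate_workflow(config, out, report)
    except Exception as exc:
        stage = report.get("last_stage", stage)
        report["error"] = {"stage": stage, "message": str(exc)}
        (out / "report.json").write_text(
            json.dumps(_round_floats(report), indent=2, default=str))
        raise RuntimeError(f"workflow failed at stage {stage!r}: {exc}") from exc
    report = _round_floats(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    log.info("report written to %s", out / "report.json")
    return report


def _sim_params(config):
    sim = dict(config.simulate)
    n_side = sim.get("n_side", 5)
    step = sim.get("step_um", 0.2)
    return sim, raster_shift_grid(n_side, step)


def _target_workflow(config, out, report):
    sim = dict(config.simulate)
    n_side = sim.get("n_side", 10)
    step = sim.get("step_um", 0.1)
    canvas = sim.get("canvas", 80)
    hr_pitch = sim.get("hr_pixel_size", 0.1)
    psf_fwhm = config.sr.get("psf_fwhm", 0.59)
    noise_sigma = sim.get("noise_sigma", 0.0)
    n_profiles = config.resolution.get("n_profiles", 8)
    shifts = raster_shift_grid(n_side, step)
    psf = PSFModel(fwhm=psf_fwhm)

    for axis in ("x", "y"):
        report["last_stage"] = f"simulate_edge_{axis}"
        edge = make_edge_target(canvas, sim.get("edge_position", canvas // 2),
                                axis=axis, pixel_size=hr_pitch)
        k_guess = config.sr.get("k") or choose_decimation(len(shifts))
        series = simulate_map_series(edge, shifts, psf, k_guess,
                                     noise_sigma=noise_sigma, seed=config.seed)
        report["last_stage"] = f"superres_{axis}"
        sr_cfg = SRConfig(k=k_guess,
                          lambda_reg=config.sr.get("lambda_reg", 0.01),
                          alpha=config.sr.get("alpha", 0.7),
                          P=config.sr.get("P", 2),
                          beta=config.sr.get("beta"),
                          n_iter=config.sr.get("n_iter", 50),
                          tol=config.sr.get("tol", 1e-6))
        result = solve_super_resolution(series, psf, sr_cfg)
        report["last_stage"] = f"resolution_{axis}"
        lr_est = step_edge_resolution(series.maps[0], axis=axis,
                                      n_profiles=min(n_profiles, series.shape[0]))
        sr_est = step_edge_resolution(result.map, axis=axis,
                                      n_profiles=n_profiles)
        save_map(result.map, out / f"sr_edge_{axis}.h5")
        report["artifacts"][f"sr_edge_{axis}"] = str(out / f"sr_edge_{axis}.h5")
        report["metrics"][axis] = {
            "k": k_guess,
            "sr_shape": list(result.map.values.shape),
            "lr_fwhm_mean_um": lr_est.fwhm_mean,
            "lr_fwhm_std_um": lr_est.fwhm_std,
            "sr_fwhm_mean_um": sr_est.fwhm_mean,
            "sr_fwhm_std_um": sr_est.fwhm_std,
            "n_profiles": sr_est.n_profiles,
            "objective_final": result.objective_trace[-1],
            "converged": result.converged,
        }


def _make_aerosol_cubes(config):
    sim, shifts = _sim_params(config)
    scene = make_mixture_scene(
        n_components=sim.get("n_components", 5),
        include_background=sim.get("include_background", False),
        hr_shape=tuple(sim.get("hr_shape", (60, 30))),
        hr_pixel_size=sim.get("hr_pixel_size", 0.2),
        noise_sigma=sim.get("noise_sigma", 0.02),
        seed=config.seed,
    )
    psf = PSFModel(fwhm=config.sr.get("psf_fwhm", 0.59))
    k = config.sr.get("k") or choose_decimation(len(shifts))
    cubes = simulate_cube_series(scene, shifts, psf, k,
                                 baseline_scale=sim.get("baseline_scale", 0.5),
                                 seed=config.seed)
    return scene, cubes, shifts, psf, k


def _aerosol_workflow(config, out, report):
    report["last_stage"] = "simulate_cubes"
    scene, cubes, shifts, psf, k = _make_aerosol_cubes(config)
    report["metrics"]["n_cubes"] = len(cubes)

    report["last_stage"] = "baseline"
    if config.baseline.get("enabled", True):
        # p = 0.05 keeps the baseline mid-noise instead of at the lower
        # envelope, which would bias corrected spectra and eat weak bands
        params = BaselineParams(lam=config.baseline.get("lam", 1e5),
                                p=config.baseline.get("p", 0.05),
                                max_iter=config.baseline.get("max_iter", 10))
        cubes = [correct_cube(c, params) for c in cubes]

    report["last_stage"] = "multiset"
    multiset = augment_multiset(cubes)
    report["metrics"]["n_spectra"] = int(multiset.data.shape[0])

    report["last_stage"] = "mcr"
    ncomp = config.mcr.get("n_components",
                           scene.n_components)
    est = MCRALS(n_components=ncomp,
                 tol=config.mcr.get("tol", 1e-3),
                 max_iter=config.mcr.get("max_iter", 50),
                 nonneg_mode=config.mcr.get("nonneg_mode", "nnls"),
                 alpha=config.mcr.get("alpha", 0.05)).fit(multiset)
    np.savetxt(out / "pure_spectra.tsv",
               np.column_stack([multiset.wavenumbers, est.St_.T]),
               delimiter="\t", header="wavenumber\t" + "\t".join(
                   f"component_{i + 1}" for i in range(ncomp)))
    report["artifacts"]["pure_spectra"] = str(out / "pure_spectra.tsv")
    report["metrics"].update(lof_percent=est.lof_, r2_percent=est.r2_,
                             mcr_iterations=est.n_iter_,
                             mcr_converged=bool(est.converged_),
                             n_components=ncomp)

    report["last_stage"] = "refold"
    per_component_series = []
    for comp in range(ncomp):
        frames = []
        for block in range(multiset.n_blocks):
            frames.append(refold_maps(multiset, est.C_, which_block=block)[comp])
        per_component_series.append(ShiftedMapSeries(
            maps=frames, shifts=shifts, lr_pixel_size=frames[0].pixel_size))

    report["last_stage"] = "superres"
    sr_cfg = SRConfig(k=k, lambda_reg=config.sr.get("lambda_reg", 0.01),
                      alpha=config.sr.get("alpha", 0.7),
                      P=config.sr.get("P", 2), beta=config.sr.get("beta"),
                      n_iter=config.sr.get("n_iter", 50),
                      tol=config.sr.get("tol", 1e-6))
    components = []
    for comp, series in enumerate(per_component_series):
        result = solve_super_resolution(series, psf, sr_cfg)
        path = out / f"sr_component_{comp + 1}.h5"
        save_map(result.map, path)
        report["artifacts"][f"sr_component_{comp + 1}"] = str(path)
        components.append({
            "component": comp + 1,
            "n_lr_maps": len(series.maps),
            "lr_shape": list(series.shape),
            "sr_shape": list(result.map.values.shape),
            "sr_pixel_size_um": result.map.pixel_size,
            "objective_final": result.objective_trace[-1],
            "converged": result.converged,
        })
    report["metrics"]["k"] = k
    report["metrics"]["components"] = components


def _simulate_workflow(config, out, report):
    report["last_stage"] = "simulate_cubes"
    scene, cubes, shifts, psf, k = _make_aerosol_cubes(config)
    manifest = {"shifts_um": shifts.tolist(), "k": k, "cubes": []}
    for i, cube in enumerate(cubes):
        path = out / f"cube_{i:03d}.h5"
        save_cube(cube, path)
        manifest["cubes"].append(str(path))
    for comp, m in enumerate(scene.hr_truth):
        save_map(m, out / f"truth_component_{comp + 1}.h5")
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    report["artifacts"]["manifest"] = str(out / "manifest.yaml")
    report["metrics"].update(n_cubes=len(cubes),
                             n_components=scene.n_components,
                             cube_shape=list(cubes[0].intensities.shape))
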