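"""Configuration loading, exporters, run manifests, and the command line.

Configuration is a TOML file with ``[simulation]``, ``[material]``,
``[specimen]`` and ``[experiment]`` tables; every key has a documented
default, so an empty file is a valid configuration.  Curves and particle
snapshots are written as CSV (17-significant-digit floats, so identical runs
produce byte-identical files) and legacy-ASCII VTK point clouds.  Every CLI
run ends by writing a JSON manifest containing the fully-resolved
configuration and seed, from which the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time as _time
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import click
import numpy as np

from . import __version__
from .material_model import MaterialParams, lame_from_elastic_moduli
from .mpm_core import GridState, ParticleState, SimConfig, advance_frame
from .clamp_interaction import ClampTrajectory
from .specimen_experiments import (
    ExperimentCurve,
    SpecimenSpec,
    make_slab,
    run_creep,
    run_relaxation,
    run_tear,
    segment_stages,
)

__all__ = [
    "ConfigError",
    "ExportError",
    "RunConfig",
    "RunManifest",
    "load_config",
    "dump_config",
    "write_curve_csv",
    "read_curve_csv",
    "write_particles_csv",
    "write_particles_vtk",
    "write_grid_csv",
    "write_manifest",
    "cli",
]


class ConfigError(ValueError):
    pass


class ExportError(RuntimeError):
    pass


DEFAULT_EXPERIMENTS: Dict[str, Dict[str, float]] = {
    "tear": {"pull_rate": 0.25, "duration": 0.8},
    "creep": {"applied_stress": 1300.0, "duration": 0.4, "load_ramp": 0.04},
    "relax": {"target_strain": 0.2, "hold_duration": 0.3, "ramp_duration": 0.2},
}

_KNOWN_TABLES = ("simulation", "material", "specimen", "experiment", "clamp")


@dataclass
class RunConfig:
    sim: SimConfig
    material: MaterialParams
    specimen: SpecimenSpec
    experiment: Dict[str, Any] = field(default_factory=dict)
    clamp: Dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, Any]:
        def clean(obj):
            d = dataclasses.asdict(obj)
            return {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in d.items()
                if v is not None
            }

        return {
            "simulation": clean(self.sim),
            "material": clean(self.material),
            "specimen": clean(self.specimen),
            "experiment": dict(self.experiment),
            "clamp": dict(self.clamp),
        }


def _build(cls, table: Dict[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in table.items():
        if key not in fields:
            warnings.warn(f"unknown config key [{name}].{key} ignored", stacklevel=3)
            continue
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] configuration: {exc}") from exc


def load_config(path: Optional[os.PathLike | str] = None) -> RunConfig:
    """Load and validate a TOML configuration; all keys are defaulted.

    The ``[material]`` table accepts either explicit ``mu0``/``lambda0`` or
    the pair ``youngs_modulus``/``poisson_ratio``.  Unknown keys warn;
    invalid values raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        data: Dict[str, Any] = {}
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        with open(p, "rb") as fh:
            try:
                data = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"malformed TOML in {p}: {exc}") from exc
    for key in data:
        if key not in _KNOWN_TABLES:
            warnings.warn(f"unknown config table [{key}] ignored", stacklevel=2)

    mat_table = dict(data.get("material", {}))
    if "youngs_modulus" in mat_table or "poisson_ratio" in mat_table:
        try:
            E = float(mat_table.pop("youngs_modulus", 10e3))
            nu = float(mat_table.pop("poisson_ratio", 0.4))
            mu, lam = lame_from_elastic_moduli(E, nu)
        except ValueError as exc:
            raise ConfigError(f"invalid [material] configuration: {exc}") from exc
        mat_table.setdefault("mu0", mu)
        mat_table.setdefault("lambda0", lam)

    sim = _build(SimConfig, data.get("simulation", {}), "simulation")
    material = _build(MaterialParams, mat_table, "material")
    specimen = _build(SpecimenSpec, data.get("specimen", {}), "specimen")

    experiment = dict(data.get("experiment", {}))
    kind = experiment.setdefault("kind", "relax")
    if kind not in DEFAULT_EXPERIMENTS:
        raise ConfigError(
            f"invalid [experiment].kind: {kind!r} (choose from "
            f"{sorted(DEFAULT_EXPERIMENTS)})"
        )
    merged = dict(DEFAULT_EXPERIMENTS[kind])
    for key, value in experiment.items():
        if key == "kind":
            continue
        if key not in merged:
            warnings.warn(f"unknown config key [experiment].{key} ignored", stacklevel=2)
            continue
        merged[key] = float(value)
    merged["kind"] = kind
    clamp = dict(data.get("clamp", {}))
    return RunConfig(sim=sim, material=material, specimen=specimen,
                     experiment=merged, clamp=clamp)


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ExportError(f"cannot serialise config value {value!r}")


def dump_config(cfg: RunConfig) -> str:
    """Serialise a configuration back to TOML (round-trips with load)."""
    lines = []
    for table, entries in cfg.to_dict().items():
        if not entries:
            continue
        lines.append(f"[{table}]")
        for key in sorted(entries):
            lines.append(f"{key} = {_toml_value(entries[key])}")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# exporters

_FMT = "%.17g"


def _require_finite(array: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(array)):
        raise ExportError(f"refusing to export non-finite values in {what}")


def write_curve_csv(curve: ExperimentCurve, path) -> None:
    data = np.column_stack([curve.time, curve.strain, curve.stress, curve.force])
    _require_finite(data, "experiment curve")
    with open(path, "w") as fh:
        fh.write("time,strain,stress,force\n")
        for row in data:
            fh.write(",".join(_FMT % v for v in row) + "\n")


def read_curve_csv(path) -> ExperimentCurve:
    data = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
    return ExperimentCurve(
        time=data[:, 0], strain=data[:, 1], stress=data[:, 2], force=data[:, 3]
    )


def write_particles_csv(particles: ParticleState, path) -> None:
    d = particles.d
    J = np.linalg.det(particles.F)
    cols = [particles.x[:, a] for a in range(d)]
    cols += [particles.v[:, a] for a in range(d)]
    cols += [J, particles.J_P, particles.status.astype(float)]
    data = np.column_stack(cols)
    _require_finite(data, "particle snapshot")
    header = (
        [f"x{a}" for a in range(d)]
        + [f"v{a}" for a in range(d)]
        + ["J", "J_P", "status"]
    )
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in data:
            fh.write(",".join(_FMT % v for v in row) + "\n")


def write_particles_vtk(particles: ParticleState, path) -> None:
    """Legacy-ASCII VTK polydata point cloud with J, J_P and status fields."""
    x = particles.x
    _require_finite(x, "particle positions")
    n, d = x.shape
    pts = np.zeros((n, 3))
    pts[:, :d] = x
    J = np.linalg.det(particles.F)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("softmpm particle snapshot\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} double\n")
        for p in pts:
            fh.write(" ".join(_FMT % v for v in p) + "\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, values in (("J", J), ("J_P", particles.J_P),
                             ("status", particles.status.astype(float))):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in values:
                fh.write(_FMT % v + "\n")


def write_grid_csv(grid: GridState, cfg: SimConfig, path) -> None:
    """Active-node diagnostics: index, mass, momentum components."""
    mass = grid.mass.reshape(-1)
    mom = grid.momentum.reshape(-1, cfg.d)
    active = np.flatnonzero(mass > 0)
    with open(path, "w") as fh:
        fh.write("node," + ",".join(f"i{a}" for a in range(cfg.d))
                 + ",mass," + ",".join(f"mv{a}" for a in range(cfg.d)) + "\n")
        for flat in active:
            idx = np.unravel_index(flat, cfg.domain_extent)
            row = [str(flat), *map(str, idx), _FMT % mass[flat]]
            row += [_FMT % v for v in mom[flat]]
            fh.write(",".join(row) + "\n")


@dataclass
class RunManifest:
    """Everything needed to replay a run exactly."""

    config: Dict[str, Any]
    seed: int
    version: str
    command: str
    outputs: Dict[str, str]
    wall_time_s: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def write_manifest(manifest: RunManifest, path) -> None:
    """Atomic write: the manifest appears only once complete."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(manifest.to_json() + "\n")
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# command line

_RUNNERS = {"tear": run_tear, "creep": run_creep, "relax": run_relaxation}


def _progress_logger(label: str, every: int = 1000):
    def progress(frame: int, total: int) -> None:
        if frame % every == 0 or frame == total:
            click.echo(f"[{label}] frame {frame}/{total}")

    return progress


def _apply_overrides(cfg: RunConfig, seed: Optional[int], frames: Optional[int]):
    if seed is not None:
        cfg.sim = dataclasses.replace(cfg.sim, seed=seed)
    if frames is not None:
        kind = cfg.experiment.get("kind", "relax")
        if kind == "relax":
            cfg.experiment["hold_duration"] = frames * cfg.sim.dt
        else:
            cfg.experiment["duration"] = frames * cfg.sim.dt
    return cfg


@click.group()
@click.version_option(version=__version__)
def cli() -> None:
    """Soft-tissue MPM simulator: characterization runs and clamp demos."""


@cli.command("run")
@click.argument("experiment", type=click.Choice(sorted(_RUNNERS)))
@click.option("--config", "config_path", type=click.Path(), default=None,
              help="TOML configuration file (defaults apply if omitted).")
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--frames", type=int, default=None,
              help="Override the run length in frames.")
def run_command(experiment, config_path, out_dir, seed, frames):
    """Run a characterization experiment and write curve + manifest."""
    t0 = _time.perf_counter()
    try:
        cfg = load_config(config_path)
    except ConfigError as exc:
        click.echo(f"configuration error: {exc}", err=True)
        raise SystemExit(2)
    cfg.experiment["kind"] = experiment
    merged = dict(DEFAULT_EXPERIMENTS[experiment])
    merged.update(
        {k: v for k, v in cfg.experiment.items() if k in merged}
    )
    cfg.experiment = {"kind": experiment, **merged}
    cfg = _apply_overrides(cfg, seed, frames)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kwargs = {k: v for k, v in cfg.experiment.items() if k != "kind"}
    try:
        curve = _RUNNERS[experiment](
            cfg.specimen, cfg.sim, cfg.material,
            seed=cfg.sim.seed, progress=_progress_logger(experiment), **kwargs,
        )
    except Exception as exc:
        click.echo(f"runtime error: {exc}", err=True)
        raise SystemExit(1)

    curve_path = out / f"{experiment}_curve.csv"
    write_curve_csv(curve, curve_path)
    outputs = {"curve": str(curve_path)}
    if experiment == "tear":
        seg = segment_stages(curve)
        seg_path = out / "tear_stages.json"
        seg_path.write_text(json.dumps(
            {"labels": seg.labels, "breakpoints": seg.breakpoints}, indent=2
        ) + "\n")
        outputs["stages"] = str(seg_path)
    manifest = RunManifest(
        config=cfg.to_dict(), seed=cfg.sim.seed, version=__version__,
        command=f"run {experiment}", outputs=outputs,
        wall_time_s=_time.perf_counter() - t0,
    )
    write_manifest(manifest, out / "manifest.json")
    click.echo(f"wrote {curve_path}")


@cli.command("clamp-demo")
@click.option("--trajectory", type=click.Path(exists=False), required=True,
              help="Clamp trajectory CSV (time, position, angle/quat, opening).")
@click.option("--config", "config_path", type=click.Path(), default=None)
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--seed", type=int, default=None)
@click.option("--frames", type=int, default=None)
def clamp_demo(trajectory, config_path, out_dir, seed, frames):
    """Drive the clamp along a keyframed trajectory and log the force."""
    t0 = _time.perf_counter()
    try:
        cfg = load_config(config_path)
        if not Path(trajectory).exists():
            raise ConfigError(f"trajectory file not found: {trajectory}")
        cfg = _apply_overrides(cfg, seed, None)
        clamp_cfg = cfg.clamp
        half = clamp_cfg.get("box_half_extent", [0.01] * cfg.sim.d)
        thresh = float(clamp_cfg.get("closed_threshold", 0.004))
        traj = ClampTrajectory.from_csv(
            trajectory, box_half_extent=half, closed_threshold=thresh, d=cfg.sim.d
        )
    except (ConfigError, ValueError) as exc:
        click.echo(f"configuration error: {exc}", err=True)
        raise SystemExit(2)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if frames is None:
        frames = int(round((traj.times[-1] - traj.times[0]) / cfg.sim.dt))
    try:
        particles = make_slab(cfg.specimen, cfg.sim, seed=cfg.sim.seed)
        grid = GridState.zeros(cfg.sim)
        log_path = out / "force_log.csv"
        with open(log_path, "w") as fh:
            fh.write("frame,time," + ",".join(f"f{a}" for a in range(cfg.sim.d)) + "\n")
            pose_n = traj.pose_at(0.0)
            for k in range(frames):
                pose_n1 = traj.pose_at((k + 1) * cfg.sim.dt)
                force = advance_frame(
                    particles, grid, cfg.material, cfg.sim,
                    clamp_n=pose_n, clamp_n1=pose_n1, frame=k,
                )
                if not np.all(np.isfinite(force)):
                    raise ExportError(f"non-finite force at frame {k}")
                fh.write(f"{k},{(k + 1) * cfg.sim.dt:.9g},"
                         + ",".join(_FMT % f for f in force) + "\n")
                pose_n = pose_n1
        write_particles_vtk(particles, out / "final_particles.vtk")
    except Exception as exc:
        click.echo(f"runtime error: {exc}", err=True)
        raise SystemExit(1)
    manifest = RunManifest(
        config=cfg.to_dict(), seed=cfg.sim.seed, version=__version__,
        command="clamp-demo", outputs={"force_log": str(log_path)},
        wall_time_s=_time.perf_counter() - t0,
    )
    write_manifest(manifest, out / "manifest.json")
    click.echo(f"wrote {log_path}")


@cli.command("make-specimen")
@click.option("--config", "config_path", type=click.Path(), default=None)
@click.option("--out-dir", type=click.Path(), default="out", show_default=True)
@click.option("--seed", type=int, default=None)
def make_specimen(config_path, out_dir, seed):
    """Sample the specimen slab and export it as CSV and VTK."""
    t0 = _time.perf_counter()
    try:
        cfg = load_config(config_path)
        cfg = _apply_overrides(cfg, seed, None)
        particles = make_slab(cfg.specimen, cfg.sim, seed=cfg.sim.seed)
    except (ConfigError, ValueError) as exc:
        click.echo(f"configuration error: {exc}", err=True)
        raise SystemExit(2)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "specimen.csv"
    vtk_path = out / "specimen.vtk"
    write_particles_csv(particles, csv_path)
    write_particles_vtk(particles, vtk_path)
    manifest = RunManifest(
        config=cfg.to_dict(), seed=cfg.sim.seed, version=__version__,
        command="make-specimen",
        outputs={"csv": str(csv_path), "vtk": str(vtk_path)},
        wall_time_s=_time.perf_counter() - t0,
    )
    write_manifest(manifest, out / "manifest.json")
    click.echo(f"wrote {csv_path} ({particles.n} particles)")


def main() -> None:  # pragma: no cover - thin wrapper
    cli()
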