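"""End-to-end run configuration and pipeline.

A single TOML configuration drives the stages: synthetic geometry →
continuum equilibrium solve → profile-based rates → kinetic IV /
conductance curves.  Physical quantities in the configuration carry
explicit unit strings that are validated at load time; outputs are CSV
tables with unit headers, OpenDX grids and a JSON run report whose file
manifest carries checksums.  The whole run is a pure function of
(config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .bikerman import default_params
from .geometry import (
    default_kcsa_spec,
    geometry_from_atoms,
    make_geometry,
    reduced_grid,
)
from .kinetics import (
    TABLE_ADJUSTED,
    TABLE_RAW_MD,
    DriveConditions,
    RateSet,
    conductance_concentration,
    cycle_balance,
    enforce_reversibility,
    iv_curve,
)
from .profiles import GaussianFeature, SyntheticProfileSpec, make_profile
from .rates import rates_vs_voltage
from .solver import SolverOptions, line_density, solve_equilibrium

__all__ = ["RunConfig", "RunReport", "StageError", "run_pipeline", "write_results"]

#: Units accepted for each configurable quantity.
_EXPECTED_UNITS = {
    "h": {"angstrom", "A"},
    "voltage": {"mV"},
    "concentration": {"M", "mol/L"},
    "temperature": {"K"},
    "diffusion_coefficient": {"A2/ps"},
    "eps_sf": {"dimensionless", ""},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _quantity(raw, expected_key: str, field_name: str) -> float:
    """Read {value=…, unit=…} with unit validation; bare numbers rejected."""
    if not isinstance(raw, dict) or "value" not in raw or "unit" not in raw:
        raise ValueError(
            f"config field {field_name!r} must be a table with 'value' and 'unit'"
        )
    unit = raw["unit"]
    allowed = _EXPECTED_UNITS[expected_key]
    if unit not in allowed:
        raise ValueError(
            f"config field {field_name!r} has unit {unit!r}; expected one of {sorted(allowed)}"
        )
    return float(raw["value"])


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    Build from a TOML file with :meth:`from_toml`; :meth:`to_dict` /
    :meth:`from_dict` round-trip losslessly.
    """

    seed: int = 0
    outdir: str = "permeakin_out"
    stages: tuple[str, ...] = ("geometry", "continuum", "rates", "kinetics")
    # continuum
    grid_h: float = 0.5
    eps_sf: float = 1.5
    concentration: float = 0.1
    temperature: float = 300.0
    pqr_path: str | None = None
    # rates stage (synthetic interconversion profile)
    profile_diffusion: float = 0.040
    profile_noise_kcal: float = 0.25
    # kinetics
    rate_table: str = "adjusted"  # adjusted | raw-MD | raw-balanced
    v_min: float = -200.0
    v_max: float = 200.0
    v_step: float = 10.0
    gc_voltage: float = 100.0
    gc_concentrations: tuple[float, ...] = (
        0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6,
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cont = raw.get("continuum", {})
        kin = raw.get("kinetics", {})
        prof = raw.get("profile", {})
        kwargs = dict(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "permeakin_out")),
            stages=tuple(raw.get("stages", ("geometry", "continuum", "rates", "kinetics"))),
        )
        if "h" in cont:
            kwargs["grid_h"] = _quantity(cont["h"], "h", "continuum.h")
        if "eps_sf" in cont:
            kwargs["eps_sf"] = float(cont["eps_sf"])
        if "concentration" in cont:
            kwargs["concentration"] = _quantity(
                cont["concentration"], "concentration", "continuum.concentration"
            )
        if "temperature" in cont:
            kwargs["temperature"] = _quantity(
                cont["temperature"], "temperature", "continuum.temperature"
            )
        if "pqr_path" in cont:
            kwargs["pqr_path"] = str(cont["pqr_path"])
        if "diffusion_coefficient" in prof:
            kwargs["profile_diffusion"] = _quantity(
                prof["diffusion_coefficient"],
                "diffusion_coefficient",
                "profile.diffusion_coefficient",
            )
        if "noise_kcal" in prof:
            kwargs["profile_noise_kcal"] = float(prof["noise_kcal"])
        if "rate_table" in kin:
            kwargs["rate_table"] = str(kin["rate_table"])
        for key, name in (("v_min", "v_min"), ("v_max", "v_max"), ("v_step", "v_step"),
                          ("gc_voltage", "gc_voltage")):
            if key in kin:
                kwargs[name] = _quantity(kin[key], "voltage", f"kinetics.{key}")
        if "gc_concentrations" in kin:
            raw_c = kin["gc_concentrations"]
            if not isinstance(raw_c, dict) or raw_c.get("unit") not in ("M", "mol/L"):
                raise ValueError(
                    "config field 'kinetics.gc_concentrations' needs values with unit M"
                )
            kwargs["gc_concentrations"] = tuple(float(v) for v in raw_c["values"])
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        return cls.from_dict(pio.load_toml(path))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": list(self.stages),
            "continuum": {
                "h": {"value": self.grid_h, "unit": "angstrom"},
                "eps_sf": self.eps_sf,
                "concentration": {"value": self.concentration, "unit": "M"},
                "temperature": {"value": self.temperature, "unit": "K"},
                **({"pqr_path": self.pqr_path} if self.pqr_path else {}),
            },
            "profile": {
                "diffusion_coefficient": {
                    "value": self.profile_diffusion,
                    "unit": "A2/ps",
                },
                "noise_kcal": self.profile_noise_kcal,
            },
            "kinetics": {
                "rate_table": self.rate_table,
                "v_min": {"value": self.v_min, "unit": "mV"},
                "v_max": {"value": self.v_max, "unit": "mV"},
                "v_step": {"value": self.v_step, "unit": "mV"},
                "gc_voltage": {"value": self.gc_voltage, "unit": "mV"},
                "gc_concentrations": {
                    "values": list(self.gc_concentrations),
                    "unit": "M",
                },
            },
        }


@dataclass
class RunReport:
    """Per-stage status, solver diagnostics and the output manifest."""

    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "stages": self.stages,
                "manifest": self.manifest,
                "wall_time_s": self.wall_time_s,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _select_rates(name: str) -> RateSet:
    if name == "adjusted":
        return TABLE_ADJUSTED
    if name == "raw-MD":
        return TABLE_RAW_MD
    if name == "raw-balanced":
        return enforce_reversibility(TABLE_RAW_MD)
    raise ValueError(f"unknown rate table {name!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the requested stages in order, writing all artifacts.

    A failing stage raises :class:`StageError` after being recorded in
    the report written so far; stages are never silently skipped.
    """
    t_start = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), seed=config.seed)
    written: list[Path] = []

    geometry = None
    params = default_params(config.concentration)

    def record(stage: str, **info) -> None:
        report.stages[stage] = {"status": "ok", **info}

    try:
        if "geometry" in config.stages:
            stage = "geometry"
            grid = reduced_grid(config.grid_h)
            if config.pqr_path:
                atoms = pio.read_pqr(config.pqr_path)
                geometry = geometry_from_atoms(
                    atoms, grid, eps_sf=config.eps_sf
                )
                record(stage, source="pqr", atoms=len(atoms))
            else:
                spec = default_kcsa_spec()
                geometry = make_geometry(spec, grid, eps_sf=config.eps_sf)
                record(
                    stage,
                    source="synthetic",
                    cells=int(np.prod(grid.shape)),
                    total_charge_e0=geometry.total_charge,
                )
            path = outdir / "epsilon.dx"
            pio.write_dx(path, geometry.eps, geometry.grid, "relative permittivity")
            written.append(path)

        if "continuum" in config.stages:
            stage = "continuum"
            if geometry is None:
                raise RuntimeError("continuum stage requires the geometry stage")
            state = solve_equilibrium(geometry, params, SolverOptions())
            density = line_density(state, geometry)
            for name, arr in (("phi", state.phi), ("K", state.p), ("Cl", state.n)):
                path = outdir / f"{name}.dx"
                pio.write_dx(
                    path, arr, geometry.grid,
                    f"{name}: potential kT/e or concentration M",
                )
                written.append(path)
            path = outdir / "line_density.csv"
            pio.write_table(path, {"z_A": density.z, "lambda_per_A": density.lam})
            written.append(path)
            path = outdir / "occupancy.csv"
            pio.write_table(
                path,
                {
                    "site": list(density.occupancy),
                    "ions": list(density.occupancy.values()),
                },
            )
            written.append(path)
            record(
                stage,
                iterations=state.iterations,
                residual=state.residual,
                occupancy=density.occupancy,
            )

        if "rates" in config.stages:
            stage = "rates"
            spec = SyntheticProfileSpec(
                x_min=0.0,
                x_max=12.0,
                features=(
                    GaussianFeature(3.0, 0.5, -5.5),
                    GaussianFeature(6.0, 0.8, 2.5),
                    GaussianFeature(9.0, 0.5, -5.0),
                ),
                diffusion_coefficient=config.profile_diffusion,
                noise_kcal=config.profile_noise_kcal,
                seed=config.seed,
            )
            profile = make_profile(spec, config.temperature).with_landmarks(
                i=3.0, b=6.0, f=9.0
            )
            voltages = np.arange(config.v_min, config.v_max + 1e-9, config.v_step)
            table = rates_vs_voltage(profile, voltages)
            path = outdir / "rates_vs_voltage.csv"
            pio.write_table(path, {"V_mV": table["V_mV"], "kf_per_s": table["k_f"],
                                   "kb_per_s": table["k_b"]})
            written.append(path)
            record(stage, kf0=float(table["k_f"][len(voltages) // 2]),
                   kb0=float(table["k_b"][len(voltages) // 2]))

        if "kinetics" in config.stages:
            stage = "kinetics"
            rates = _select_rates(config.rate_table)
            ratios = cycle_balance(rates)
            drive = DriveConditions(
                0.0, config.concentration, config.concentration, config.temperature
            )
            voltages = np.arange(config.v_min, config.v_max + 1e-9, config.v_step)
            iv = iv_curve(rates, drive, voltages)
            path = outdir / "iv.csv"
            pio.write_table(path, iv)
            written.append(path)
            gc = conductance_concentration(
                rates, config.gc_voltage, config.gc_concentrations, config.temperature
            )
            path = outdir / "conductance.csv"
            pio.write_table(path, gc)
            written.append(path)
            i0 = float(np.interp(0.0, iv["V_mV"], iv["I_pA"]))
            record(stage, cycle_ratios=list(ratios), i_at_0mV_pA=i0)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        report.stages[stage] = {"status": "failed", "error": str(exc)}
        _finalise(report, written, outdir, t_start)
        raise StageError(stage, exc) from exc

    _finalise(report, written, outdir, t_start)
    return report


def _finalise(report: RunReport, written: list[Path], outdir: Path, t0: float) -> None:
    report.wall_time_s = time.monotonic() - t0
    report.manifest = {p.name: _sha256(p) for p in written}
    (outdir / "report.json").write_text(report.to_json())


def write_results(tables: dict, grids: dict, report: RunReport, outdir) -> dict[str, str]:
    """Write CSV tables, OpenDX grids and the JSON report; return manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, cols in tables.items():
        path = outdir / f"{name}.csv"
        pio.write_table(path, cols)
        manifest[path.name] = _sha256(path)
    for name, (field_arr, grid) in grids.items():
        path = outdir / f"{name}.dx"
        pio.write_dx(path, field_arr, grid)
        manifest[path.name] = _sha256(path)
    report.manifest.update(manifest)
    path = outdir / "report.json"
    path.write_text(report.to_json())
    manifest[path.name] = _sha256(path)
    return manifest
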