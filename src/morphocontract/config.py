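"""Run configuration and command dispatch.

A ``RunConfig`` fully determines a run: the command, parameter overrides,
scenario descriptor, numerical settings and output directory.  Unknown keys
are rejected; omissions are filled with the published defaults.  ``run``
dispatches to the library modules and writes CSV tables, VTK snapshots and a
reproducibility manifest; there is no hidden global state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import ModelParameters, StrainEquilibrium
from .fem.mesh import build_mesh
from .fem.solver import (
    PicardConfig,
    Simulator,
    TimeStepperConfig,
    convergence_study,
)
from .scenarios import (
    PerturbationScenario,
    WoundScenario,
    perturbation_initial_conditions,
    wound_initial_conditions,
)
from .stability import (
    WaveMode,
    GridSpec,
    assemble_semidiscrete_matrix,
    assemble_mode_matrix,
    chemical_conditions,
    semidiscrete_conditions,
    stability_map,
)
from . import io as mio

__all__ = ["RunConfig", "run"]

COMMANDS = ("stability-map", "modes", "simulate", "converge")


def _from_mapping(cls, mapping: dict, label: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {label} keys: {sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class RunConfig:
    command: str
    output_dir: str = "morphocontract-out"
    parameters: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ValueError(f"unknown command {self.command!r}; expected one of {COMMANDS}")
        for key in self.numerics:
            if key not in ("picard", "stepper"):
                raise ValueError(f"unknown numerics key: {key}")

    # -- resolution -------------------------------------------------------

    def resolved_parameters(self) -> ModelParameters:
        return ModelParameters.defaults(**self.parameters)

    def picard(self) -> PicardConfig:
        return _from_mapping(PicardConfig, self.numerics.get("picard", {}), "picard")

    def stepper(self) -> TimeStepperConfig:
        return _from_mapping(TimeStepperConfig, self.numerics.get("stepper", {}), "stepper")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return _from_mapping(cls, payload, "config")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run(config: RunConfig) -> dict[str, Path]:
    """Execute a run and write its artifacts; returns paths by kind."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.resolved_parameters()
    dispatch = {
        "stability-map": _run_stability_map,
        "modes": _run_modes,
        "simulate": _run_simulate,
        "converge": _run_converge,
    }
    artifacts = dispatch[config.command](config, params, out)
    manifest = out / "manifest.yaml"
    mio.write_manifest(
        config.to_dict(), manifest,
        resolved_parameters=params.to_dict(),
        artifacts={k: str(v) for k, v in artifacts.items()},
    )
    artifacts["manifest"] = manifest
    return artifacts


def _opt(config: RunConfig, key: str, default):
    return config.options.get(key, default)


def _run_stability_map(config: RunConfig, params: ModelParameters, out: Path):
    step = float(_opt(config, "strain_step", 0.1))
    lo, hi = _opt(config, "strain_range", (-1.0, 1.0))
    axis = np.round(np.arange(lo, hi + 0.5 * step, step), 12)
    e12_levels = np.asarray(_opt(config, "e12_levels", [-1.0, -0.5, 0.0, 0.5]), float)
    l_max, p_max = _opt(config, "mode_range", (100, 100))
    result = stability_map(params, axis, axis, e12_levels, (int(l_max), int(p_max)))
    rows = []
    for k, e12 in enumerate(result.e12_levels):
        for i, e11 in enumerate(result.e11_axis):
            for j, e22 in enumerate(result.e22_axis):
                rows.append((e11, e22, e12, result.S[k, i, j]))
    frame = pd.DataFrame(rows, columns=["e11", "e22", "e12", "S"])
    csv = out / "stability_map.csv"
    frame.to_csv(csv, index=False)
    artifacts = {"stability_map": csv}
    if _opt(config, "plot", False):
        artifacts["plot"] = _plot_map(result, out / "stability_map.png")
    return artifacts


def _plot_map(result, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k_levels = result.e12_levels.size
    fig, axes = plt.subplots(1, k_levels, figsize=(3.2 * k_levels, 3.0), squeeze=False)
    for k, ax in enumerate(axes[0]):
        ax.pcolormesh(
            result.e11_axis, result.e22_axis, result.S[k].T,
            cmap="RdBu", vmin=0, vmax=1, shading="nearest",
        )
        ax.set_title(f"e12 = {result.e12_levels[k]:g}")
        ax.set_xlabel("e11")
        ax.set_ylabel("e22")
        ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _run_modes(config: RunConfig, params: ModelParameters, out: Path):
    strain = StrainEquilibrium(*_opt(config, "strain_eq", (0.0, 0.0, 0.0)))
    l_max, p_max = _opt(config, "mode_range", (10, 10))
    semidiscrete = bool(_opt(config, "semidiscrete", False))
    h = float(_opt(config, "h", 0.1))
    rows = []
    for l in range(0, int(l_max) + 1):
        for p in range(0, int(p_max) + 1):
            mode = WaveMode(l, p)
            if semidiscrete:
                grid = GridSpec.from_spacing(h)
                system = assemble_semidiscrete_matrix(params, strain, mode, grid)
                cond = semidiscrete_conditions(params, mode, grid)
            else:
                system = assemble_mode_matrix(params, strain, mode)
                cond = chemical_conditions(params, mode)
            eigs = np.linalg.eigvals(system.mechanical_block)
            eigs = eigs[np.argsort(eigs.real)]
            row = {"l": l, "p": p}
            row.update({f"chem_{name}": cond[i] for i, name in
                        enumerate(("N", "M", "c", "rho"))})
            if semidiscrete:
                row["mech_condition"] = cond[4]
            for i, lam in enumerate(eigs):
                row[f"mech_eig{i}_re"] = lam.real
                row[f"mech_eig{i}_im"] = lam.imag
            rows.append(row)
    csv = out / ("modes_semidiscrete.csv" if semidiscrete else "modes.csv")
    pd.DataFrame(rows).to_csv(csv, index=False)
    return {"modes": csv}


def _run_simulate(config: RunConfig, params: ModelParameters, out: Path):
    scen = dict(config.scenario)
    kind = scen.pop("kind", "perturbation")
    T = float(_opt(config, "T", 10.0))
    h = float(_opt(config, "h", 0.05))
    if kind == "perturbation":
        L = float(_opt(config, "L", 1.0))
        scenario = _from_mapping(PerturbationScenario, scen, "perturbation scenario")
        mesh = build_mesh(L, h)
        state0 = perturbation_initial_conditions(mesh, scenario, params)
    elif kind == "wound":
        scenario = _from_mapping(WoundScenario, scen, "wound scenario")
        mesh = build_mesh(scenario.domain_side, h)
        state0 = wound_initial_conditions(mesh, scenario, params)
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    sim = Simulator(mesh, params, picard=config.picard(), stepper=config.stepper())
    track = [tuple(xy) for xy in _opt(config, "track_points", [(0.0, 0.0)])]
    snap_times = list(_opt(config, "snapshot_times", []))
    result = sim.run(state0, T, track_points=track, snapshot_times=snap_times)
    csv = out / "timeseries.csv"
    mio.export_timeseries(result, csv)
    log = out / "runlog.csv"
    pd.DataFrame(
        {"time": result.times, "mesh_quality": result.quality_trace,
         "picard_iterations": result.picard_trace}
    ).to_csv(log, index=False)
    artifacts = {"timeseries": csv, "runlog": log}
    for k, (t_snap, state) in enumerate(result.snapshots):
        vtk = out / f"snapshot_{k:03d}.vtk"
        mio.write_vtk(sim.mesh0.moved(state.u), state, vtk)
        artifacts[f"snapshot_{k}"] = vtk
    final_vtk = out / "final.vtk"
    mio.write_vtk(result.mesh, result.final_state, final_vtk)
    artifacts["final"] = final_vtk
    artifacts["status"] = result.status  # type: ignore[assignment]
    return artifacts


def _run_converge(config: RunConfig, params: ModelParameters, out: Path):
    h_list = [float(h) for h in _opt(config, "h_list", (0.4, 0.2, 0.1))]
    domain = float(_opt(config, "domain", 3.2))
    T = float(_opt(config, "T", 1.0))
    report = convergence_study(h_list, params, domain=domain, T=T,
                               picard=config.picard())
    csv = out / "convergence.csv"
    report.as_table().to_csv(csv)
    return {"convergence": csv}
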