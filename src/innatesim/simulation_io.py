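"""Configuration files, result serialization and the command-line interface.

Config format: a flat TOML document with sections ``[grid]``, ``[time]``,
``[case]`` and ``[parameters]``.  Every key is optional -- an empty file
yields the standard setup (full model, 5 mm strip, dx = 0.1 mm,
dt = 1e-5 day, 5-day horizon).  ``[parameters]`` entries override individual
model parameters by symbol name; unknown keys anywhere are an error.

Outputs are plain tab-separated text: one file per species (rows = output
times, columns = grid nodes) plus one totals file, written at full float
precision so a re-read reproduces the trajectory bit-exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib
import sys
import tomllib

import click
import numpy as np
import pandas as pd

from . import __version__
from .analysis import case_comparison, convergence_study
from .model_core import SPECIES, ParameterSet
from .numerics import Grid, StabilityError, Trajectory, simulate, stability_bound
from .scenarios import build_case, default_parameters, initial_state

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "run_from_config",
    "write_snapshots",
    "read_species_file",
    "read_totals",
    "cli",
    "main",
]

logger = logging.getLogger(__name__)

_PARAM_NAMES = tuple(f.name for f in dataclasses.fields(ParameterSet))

_SCHEMA = {
    "grid": ("length", "dx"),
    "time": ("dt", "t_final", "totals_every", "snapshots_every"),
    "case": ("case",),
    "parameters": _PARAM_NAMES,
}


@dataclasses.dataclass
class RunConfig:
    """A fully validated simulation request."""

    case: int = 5
    length: float = 5.0  # mm
    dx: float = 0.1  # mm
    dt: float = 1e-5  # day
    t_final: float = 5.0  # day
    totals_every: float = 0.01  # day, cadence of the totals series
    snapshots_every: float = 0.5  # day, cadence of full spatial snapshots
    overrides: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.case not in (1, 2, 3, 4, 5):
            raise ValueError(f"config key 'case' must be in 1..5, got {self.case!r}")
        for key in ("length", "dx", "dt", "totals_every", "snapshots_every"):
            if getattr(self, key) <= 0:
                raise ValueError(f"config key '{key}' must be > 0")
        if self.t_final < 0:
            raise ValueError("config key 't_final' must be >= 0")
        for key in self.overrides:
            if key not in _PARAM_NAMES:
                raise ValueError(f"unknown parameter override {key!r}")

    def parameters(self) -> ParameterSet:
        p = default_parameters()
        return p.replace(**self.overrides) if self.overrides else p

    def grid(self) -> Grid:
        return Grid.from_spacing(self.length, self.dx)


def load_config(path) -> RunConfig:
    """Parse and validate a TOML config file; missing keys take defaults."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    for section, keys in doc.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(keys, dict):
            raise ValueError(f"config section {section!r} must be a table")
        for key in keys:
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown key {key!r} in section [{section}]")
    kwargs: dict = {}
    grid_sec = doc.get("grid", {})
    time_sec = doc.get("time", {})
    for key in ("length", "dx"):
        if key in grid_sec:
            kwargs[key] = float(grid_sec[key])
    for key in ("dt", "t_final", "totals_every", "snapshots_every"):
        if key in time_sec:
            kwargs[key] = float(time_sec[key])
    if "case" in doc.get("case", {}):
        kwargs["case"] = int(doc["case"]["case"])
    kwargs["overrides"] = {k: float(v) for k, v in doc.get("parameters", {}).items()}
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig) -> str:
    """Serialize a RunConfig to the TOML config format (round-trip exact)."""
    lines = [
        "[grid]",
        f"length = {cfg.length!r}",
        f"dx = {cfg.dx!r}",
        "",
        "[time]",
        f"dt = {cfg.dt!r}",
        f"t_final = {cfg.t_final!r}",
        f"totals_every = {cfg.totals_every!r}",
        f"snapshots_every = {cfg.snapshots_every!r}",
        "",
        "[case]",
        f"case = {cfg.case}",
    ]
    if cfg.overrides:
        lines += ["", "[parameters]"]
        lines += [f"{k} = {v!r}" for k, v in cfg.overrides.items()]
    return "\n".join(lines) + "\n"


def run_from_config(cfg: RunConfig) -> Trajectory:
    """Simulate one configuration (totals recorded at ``totals_every``)."""
    p = cfg.parameters()
    grid = cfg.grid()
    flags = build_case(cfg.case).flags
    n_out = int(round(cfg.t_final / cfg.totals_every))
    times = [i * cfg.totals_every for i in range(n_out + 1)]
    if not times or times[-1] < cfg.t_final - 1e-12:
        times.append(cfg.t_final)
    return simulate(p, flags, grid, cfg.dt, cfg.t_final, times,
                    initial=initial_state(grid))


def _fmt(v: float) -> str:
    return repr(float(v))


def write_snapshots(traj: Trajectory, outdir, snapshots_every: float | None = None):
    """Write one TSV per species plus a totals TSV into ``outdir``.

    Species files: first column the snapshot time (day), remaining columns
    the field values at the grid nodes (header row gives x in mm).  When
    ``snapshots_every`` is given, only snapshot times on that cadence are
    written (the totals file always keeps every recorded time).  Values are
    written at full precision, so re-reading is bit-exact.  Returns the list
    of written paths.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = traj.grid.x
    keep = []
    for idx, t in enumerate(traj.times):
        if snapshots_every is None:
            keep.append(idx)
        else:
            k = round(t / snapshots_every)
            if abs(t - k * snapshots_every) < 1e-9:
                keep.append(idx)
    written = []
    for k, name in enumerate(SPECIES):
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# {name}: concentration (model units) on the grid; "
                     "rows = time (day), columns = x (mm)\n")
            fh.write("time\t" + "\t".join(_fmt(v) for v in x) + "\n")
            for idx in keep:
                row = traj.states[idx].fields[k]
                fh.write(_fmt(traj.times[idx]) + "\t"
                         + "\t".join(_fmt(v) for v in row) + "\n")
        written.append(path)
    totals_path = outdir / "totals.tsv"
    with open(totals_path, "w") as fh:
        fh.write("# spatially integrated totals (conc * mm) vs time (day)\n")
        fh.write("\t".join(("time",) + SPECIES) + "\n")
        for _, row in traj.totals.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    written.append(totals_path)
    return written


def read_species_file(path):
    """Read one species TSV back: (times, x, values[time, node])."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    x = np.array([float(c) for c in df.columns[1:]])
    data = df.to_numpy(dtype=float)
    return data[:, 0], x, data[:, 1:]


def read_totals(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# command-line interface


@click.group()
@click.version_option(__version__)
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def cli(verbose: bool) -> None:
    """Simulate the innate immune response to an LPS bolus in a tissue strip."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              help="TOML configuration file.")
@click.option("--case", type=click.IntRange(1, 5), default=None,
              help="Scenario case (overrides the config).")
@click.option("--dt", type=float, default=None, help="Time step in days.")
@click.option("--t-final", type=float, default=None, help="Horizon in days.")
@click.option("--out", "outdir", type=click.Path(), default="innatesim-out",
              show_default=True, help="Output directory.")
def run(config_path, case, dt, t_final, outdir) -> None:
    """Run one simulation and write snapshot/totals files."""
    cfg = load_config(config_path) if config_path else RunConfig()
    changes = {}
    if case is not None:
        changes["case"] = case
    if dt is not None:
        changes["dt"] = dt
    if t_final is not None:
        changes["t_final"] = t_final
    if changes:
        cfg = dataclasses.replace(cfg, **changes)
    bound = stability_bound(cfg.parameters(), cfg.grid().dx)
    click.echo(f"stability bound: {bound:g} day (dt = {cfg.dt:g} day)", err=True)
    try:
        traj = run_from_config(cfg)
    except StabilityError as exc:
        raise click.ClickException(str(exc)) from exc
    paths = write_snapshots(traj, outdir, snapshots_every=cfg.snapshots_every)
    click.echo(f"wrote {len(paths)} files to {outdir}")


@cli.command()
@click.option("--axis", type=click.Choice(["time", "space"]), default="time",
              show_default=True)
@click.option("--case", type=click.IntRange(1, 5), default=5, show_default=True)
@click.option("--t-final", type=float, default=None,
              help="Horizon of the study in days (default: 0.25 for the "
                   "time axis, 5.0 for the space axis).")
def convergence(axis, case, t_final) -> None:
    """Refinement study: L2 errors against a refined reference, with ratios."""
    report = convergence_study(axis, case=case, t_final=t_final)
    click.echo(report.summary())


@cli.command("compare-cases")
@click.option("--dt", type=float, default=1e-5, show_default=True)
@click.option("--t-final", type=float, default=5.0, show_default=True)
@click.option("--out", "outdir", type=click.Path(), default=None,
              help="If given, write one total-vs-time table per species.")
def compare_cases(dt, t_final, outdir) -> None:
    """Run Cases 1-5 and report the qualitative ordering checks."""
    comp = case_comparison(dt=dt, t_final=t_final)
    if outdir is not None:
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in SPECIES:
            table = comp.species_table(name)
            path = out / f"totals_{name}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# total {name} (conc * mm) vs time (day), one column per case\n")
                table.to_csv(fh, sep="\t", index=False)
        click.echo(f"wrote comparison tables to {outdir}")
    click.echo(comp.summary())


def main() -> None:
    cli(prog_name="innatesim")
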