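"""Scripted experiments and the command-line interface.

Each experiment reads a :class:`RunConfig`, runs one pipeline (simulate /
sweep / scan1d / locus2d / classify2d / fit / make-data) and writes CSV
outputs with JSON sidecars, the resolved configuration, and a plain-text
log into the output directory — enough provenance to re-run any result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import click
import numpy as np

from .antisense import ModelVariant
from .bifurcation import scan_parameter, trace_isoperiod_locus, classify_region_grid
from .fitting import FitConstraints, ensemble_fit
from .model import MutantSpec
from .parameters import (
    ParameterSet,
    load_parameter_file,
    parse_ode_parameters,
    wt_parameters,
)
from .rhythms import (
    EQ4_CRITERIA,
    FIG3B_CRITERIA,
    RhythmCriteria,
    simulate,
    summarize_limit_cycle,
)
from .synthetic import generate_model_dataset, generate_waveform_dataset

__all__ = ["RunConfig", "run_experiment", "cli"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable description of one experiment."""

    command: str
    variant: str = "pre"
    parameter_file: Optional[str] = None
    overrides: dict = field(default_factory=dict)     # parameter overrides
    y4_0: float = 0.0
    x5_0: Optional[float] = None
    # command-specific options
    param: Optional[str] = None            # swept symbol (sweep / scan1d)
    lo: float = 0.0
    hi: float = 1.0
    n_points: int = 21
    param2: Optional[str] = None           # second axis (locus2d / classify2d)
    lo2: float = 0.0
    hi2: float = 1.0
    n_points2: int = 21
    t_target: float = 23.5                 # iso-period target (locus2d)
    criteria: str = "eq4"                  # eq4 | fig3b (classify2d)
    t_end: float = 800.0
    transient: float = 500.0
    dt: float = 0.1
    seed: int = 0
    noise_sd: float = 0.0
    n_steps: int = 500                     # fit
    free_params: tuple = ()
    outdir: str = "per2as-out"

    def resolved_params(self) -> ParameterSet:
        params = (load_parameter_file(self.parameter_file)
                  if self.parameter_file else wt_parameters())
        if self.overrides:
            params = params.replace(**self.overrides)
        return params

    def mutant(self) -> MutantSpec:
        return MutantSpec(y4_0=self.y4_0, x5_0=self.x5_0)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["free_params"] = list(self.free_params)
        return json.dumps(d, indent=2)


def _criteria(name: str) -> RhythmCriteria:
    return {"eq4": EQ4_CRITERIA, "fig3b": FIG3B_CRITERIA}[name]


def run_experiment(config: RunConfig) -> Path:
    """Dispatch a configured experiment; returns the output directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("per2as")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    params = config.resolved_params()
    mutant = config.mutant()
    (out / "config.json").write_text(config.to_json(), encoding="utf-8")
    (out / "params.json").write_text(
        json.dumps(dict(fingerprint=params.fingerprint(),
                        values=params.as_dict()), indent=2),
        encoding="utf-8")
    try:
        logger.info("running %s (variant=%s, fingerprint=%s)",
                    config.command, config.variant, params.fingerprint())
        _COMMANDS[config.command](config, params, mutant, out)
        logger.info("done in %.1f s", time.time() - t0)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _cmd_simulate(config, params, mutant, out: Path):
    traj = simulate(config.variant, params, mutant,
                    t_end=config.t_end, transient=config.transient, dt=config.dt)
    traj.to_csv(out / "trajectory.csv")
    summarize_limit_cycle(traj).to_csv(out / "summary.csv")


def _cmd_sweep(config, params, mutant, out: Path):
    """Period / amplitude / phases of every species vs one parameter."""
    import pandas as pd

    from .bifurcation import _apply

    values = np.linspace(config.lo, config.hi, config.n_points)
    rows = []
    for v in values:
        p, m = _apply(params, mutant, config.param, v)
        row = {config.param: float(v)}
        try:
            traj = simulate(config.variant, p, m, t_end=config.t_end,
                            transient=config.transient, dt=config.dt)
            s = summarize_limit_cycle(traj)
        except Exception as err:       # keep the sweep alive
            logger.warning("sweep point %s=%g failed: %s", config.param, v, err)
            row["oscillatory"] = False
            rows.append(row)
            continue
        row["oscillatory"] = s.oscillatory
        row["period_h"] = s.period
        for sp in traj.species:
            row[f"amp_{sp}"] = s.amplitude(sp)
            if s.oscillatory and sp in s.phases:
                row[f"phase_{sp}"] = s.phases[sp]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "sweep.csv", index=False)


def _cmd_scan1d(config, params, mutant, out: Path):
    diagram = scan_parameter(
        config.variant, config.param, config.lo, config.hi,
        n_points=config.n_points, params=params, mutant=mutant)
    diagram.to_csv(out / "branch.csv",
                   sidecar=dict(fingerprint=params.fingerprint()))


def _cmd_locus2d(config, params, mutant, out: Path):
    locus = trace_isoperiod_locus(
        config.variant, config.param,
        np.linspace(config.lo, config.hi, config.n_points),
        config.param2, (config.lo2, config.hi2), config.t_target,
        params=params, mutant=mutant)
    locus.to_csv(out / "locus.csv",
                 sidecar=dict(fingerprint=params.fingerprint()))


def _cmd_classify2d(config, params, mutant, out: Path):
    grid = classify_region_grid(
        config.variant, config.param,
        np.linspace(config.lo, config.hi, config.n_points),
        config.param2, np.linspace(config.lo2, config.hi2, config.n_points2),
        _criteria(config.criteria), params=params, mutant=mutant)
    grid.to_csv(out / "regions.csv", index=False)


def _cmd_make_data(config, params, mutant, out: Path):
    if config.variant == "waveform":
        ds = generate_waveform_dataset(noise_sd=config.noise_sd, seed=config.seed)
    else:
        ds = generate_model_dataset(config.variant, params, mutant,
                                    noise_sd=config.noise_sd, seed=config.seed)
    ds.to_csv(out / "dataset.csv")


def _cmd_fit(config, params, mutant, out: Path):
    ds = generate_model_dataset(config.variant, params, mutant,
                                noise_sd=config.noise_sd, seed=config.seed)
    free = list(config.free_params) or ["lam", "K_S"]
    bounds = {s: (params[s] / 5.0, params[s] * 5.0) for s in free}
    result = ensemble_fit(ds, FitConstraints(), free, bounds,
                          n_steps=config.n_steps, seed=config.seed,
                          start=params, variant=config.variant)
    result.to_csv(out / "ensemble.csv", symbols=free)
    (out / "ensemble.csv.json").write_text(json.dumps(dict(
        seed=result.seed, n_steps=result.n_steps,
        acceptance_rate=result.acceptance_rate,
        threshold=result.threshold), indent=2), encoding="utf-8")


_COMMANDS = {
    "simulate": _cmd_simulate,
    "sweep": _cmd_sweep,
    "scan1d": _cmd_scan1d,
    "locus2d": _cmd_locus2d,
    "classify2d": _cmd_classify2d,
    "make-data": _cmd_make_data,
    "fit": _cmd_fit,
}


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _common_options(f):
    f = click.option("--variant", default="pre",
                     type=click.Choice([v.value for v in ModelVariant] + ["waveform"]))(f)
    f = click.option("--parameter-file", default=None, type=click.Path(exists=True))(f)
    f = click.option("--set", "overrides", multiple=True,
                     help="parameter override name=value (repeatable)")(f)
    f = click.option("--y4-0", default=0.0, type=float)(f)
    f = click.option("--x5-0", default=None, type=float)(f)
    f = click.option("--seed", default=0, type=int)(f)
    f = click.option("--outdir", default="per2as-out", type=click.Path())(f)
    return f


def _parse_overrides(pairs) -> dict:
    out = {}
    for pair in pairs:
        name, _, value = pair.partition("=")
        if not _ or not name:
            raise click.BadParameter(f"expected name=value, got {pair!r}")
        out[name.strip()] = float(value)
    return out


def _build_config(command, variant, parameter_file, overrides, y4_0, x5_0,
                  seed, outdir, **extra) -> RunConfig:
    return RunConfig(command=command, variant=variant,
                     parameter_file=parameter_file,
                     overrides=_parse_overrides(overrides),
                     y4_0=y4_0, x5_0=x5_0, seed=seed, outdir=outdir, **extra)


@click.group()
def cli():
    """Sense-antisense Per2/Per2AS circadian-clock workbench."""


@cli.command(name="simulate")
@_common_options
@click.option("--t-end", default=800.0, type=float)
@click.option("--transient", default=500.0, type=float)
@click.option("--dt", default=0.1, type=float)
def simulate_cmd(variant, parameter_file, overrides, y4_0, x5_0, seed, outdir,
                 t_end, transient, dt):
    """Simulate to the attractor and write trajectory + summary."""
    cfg = _build_config("simulate", variant, parameter_file, overrides, y4_0,
                        x5_0, seed, outdir, t_end=t_end, transient=transient, dt=dt)
    click.echo(str(run_experiment(cfg)))


@cli.command()
@_common_options
@click.option("--param", required=True)
@click.option("--lo", required=True, type=float)
@click.option("--hi", required=True, type=float)
@click.option("--n-points", default=21, type=int)
def sweep(variant, parameter_file, overrides, y4_0, x5_0, seed, outdir,
          param, lo, hi, n_points):
    """Period/amplitude/phase of all species vs one parameter."""
    cfg = _build_config("sweep", variant, parameter_file, overrides, y4_0,
                        x5_0, seed, outdir, param=param, lo=lo, hi=hi,
                        n_points=n_points)
    click.echo(str(run_experiment(cfg)))


@cli.command()
@_common_options
@click.option("--param", required=True)
@click.option("--lo", required=True, type=float)
@click.option("--hi", required=True, type=float)
@click.option("--n-points", default=101, type=int)
def scan1d(variant, parameter_file, overrides, y4_0, x5_0, seed, outdir,
           param, lo, hi, n_points):
    """One-parameter bifurcation scan with Hopf refinement."""
    cfg = _build_config("scan1d", variant, parameter_file, overrides, y4_0,
                        x5_0, seed, outdir, param=param, lo=lo, hi=hi,
                        n_points=n_points)
    click.echo(str(run_experiment(cfg)))


@cli.command()
@_common_options
@click.option("--param", required=True, help="first axis (grid)")
@click.option("--lo", required=True, type=float)
@click.option("--hi", required=True, type=float)
@click.option("--n-points", default=11, type=int)
@click.option("--param2", required=True, help="second axis (bisection)")
@click.option("--lo2", required=True, type=float)
@click.option("--hi2", required=True, type=float)
@click.option("--t-target", default=23.5, type=float)
def locus2d(variant, parameter_file, overrides, y4_0, x5_0, seed, outdir,
            param, lo, hi, n_points, param2, lo2, hi2, t_target):
    """Iso-period locus in a two-parameter plane."""
    cfg = _build_config("locus2d", variant, parameter_file, overrides, y4_0,
                        x5_0, seed, outdir, param=param, lo=lo, hi=hi,
                        n_points=n_points, param2=param2, lo2=lo2, hi2=hi2,
                        t_target=t_target)
    click.echo(str(run_experiment(cfg)))


@cli.command()
@_common_options
@click.option("--param", required=True)
@click.option("--lo", required=True, type=float)
@click.option("--hi", required=True, type=float)
@click.option("--n-points", default=11, type=int)
@click.option("--param2", required=True)
@click.option("--lo2", required=True, type=float)
@click.option("--hi2", required=True, type=float)
@click.option("--n-points2", default=11, type=int)
@click.option("--criteria", default="eq4", type=click.Choice(["eq4", "fig3b"]))
def classify2d(variant, parameter_file, overrides, y4_0, x5_0, seed, outdir,
               param, lo, hi, n_points, param2, lo2, hi2, n_points2, criteria):
    """Classify a two-parameter grid (circadian / antiphasic regions)."""
    cfg = _build_config("classify2d", variant, parameter_file, overrides, y4_0,
                        x5_0, seed, outdir, param=param, lo=lo, hi=hi,
                        n_points=n_points, param2=param2, lo2=lo2, hi2=hi2,
                        n_points2=n_points2, criteria=criteria)
    click.echo(str(run_experiment(cfg)))


@cli.command(name="make-data")
@_common_options
@click.option("--noise-sd", default=0.0, type=float)
def make_data(variant, parameter_file, overrides, y4_0, x5_0, seed, outdir,
              noise_sd):
    """Generate a synthetic antiphasic dataset (CSV + metadata)."""
    cfg = _build_config("make-data", variant, parameter_file, overrides, y4_0,
                        x5_0, seed, outdir, noise_sd=noise_sd)
    click.echo(str(run_experiment(cfg)))


@cli.command()
@_common_options
@click.option("--noise-sd", default=0.05, type=float)
@click.option("--n-steps", default=500, type=int)
@click.option("--free", "free_params", multiple=True, default=("K_S", "d_AS"))
def fit(variant, parameter_file, overrides, y4_0, x5_0, seed, outdir,
        noise_sd, n_steps, free_params):
    """Ensemble-fit free parameters to a self-generated noisy dataset."""
    cfg = _build_config("fit", variant, parameter_file, overrides, y4_0,
                        x5_0, seed, outdir, noise_sd=noise_sd,
                        n_steps=n_steps, free_params=tuple(free_params))
    click.echo(str(run_experiment(cfg)))


@cli.command(name="parse-ode")
@click.argument("path", type=click.Path(exists=True))
def parse_ode(path):
    """Print the `par` declarations of an XPPAUT-style .ode file."""
    params = parse_ode_parameters(path)
    for key in params:
        click.echo(f"{key} = {params[key]!r}")
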