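"""Ensemble parameter estimation against antiphasic time-course data.

Rather than seeking a single optimum, the fitter runs a Metropolis random
walk in log-parameter space and keeps *every* visited parameter set whose
cost falls below a threshold — yielding an ensemble of acceptable
parameterizations, which is the natural output when many rate constants are
only weakly constrained by rhythmic data.

The cost is a weighted sum of
  (i)   mean squared error between peak-normalized model output and the
        peak-normalized data at the sample times, aligned by the best
        circular time shift (rhythmic data carry no absolute phase),
  (ii)  quadratic penalties for the period and the Per2/Per2AS phase
        difference leaving their target windows, and
  (iii) penalties for violated mutant behaviours (e.g. "oscillation is lost
        for y4_0 above 8").
All weights are configuration, not constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .antisense import ModelVariant
from .model import MutantSpec, WILD_TYPE
from .parameters import ParameterSet
from .rhythms import (
    IntegrationError,
    measure_period,
    measure_phases,
    simulate,
)
from .synthetic import TimecourseDataset

__all__ = ["FitConstraints", "MutantBehaviour", "EnsembleResult",
           "fit_cost", "ensemble_fit"]

logger = logging.getLogger(__name__)

FAILED_SIMULATION_COST = 1e6     # finite sentinel keeps samplers alive

# fitting simulations are shorter than analysis-grade ones; the rhythm
# metrics only need ~8 cycles here
_FIT_SIM = dict(t_end=720.0, transient=500.0, dt=0.1)


@dataclass(frozen=True)
class MutantBehaviour:
    """A qualitative constraint: a mutant must (not) oscillate."""

    mutant: MutantSpec
    should_oscillate: bool
    species: str = "Per2"


@dataclass(frozen=True)
class FitConstraints:
    """Target windows and weights for :func:`fit_cost`."""

    period_window: tuple[float, float] = (23.0, 25.0)
    phase_diff_window: tuple[float, float] = (11.0, 13.0)
    mutant_behaviours: tuple[MutantBehaviour, ...] = ()
    weight_timecourse: float = 1.0
    weight_period: float = 1.0
    weight_phase: float = 1.0
    weight_mutant: float = 1.0

    def __post_init__(self):
        for w in (self.weight_timecourse, self.weight_period,
                  self.weight_phase, self.weight_mutant):
            if w < 0:
                raise ValueError("weights must be >= 0")
        if self.period_window[0] >= self.period_window[1]:
            raise ValueError("empty period window")
        if self.phase_diff_window[0] >= self.phase_diff_window[1]:
            raise ValueError("empty phase window")


def _window_penalty(value: float, window: tuple[float, float]) -> float:
    lo, hi = window
    if value < lo:
        return (lo - value) ** 2
    if value > hi:
        return (value - hi) ** 2
    return 0.0


def _timecourse_sse(traj, dataset: TimecourseDataset) -> float:
    """Peak-normalized MSE at the sample times, best circular alignment.

    The model trajectory is wrapped onto one period and shifted over a grid
    of offsets; the smallest mean squared residual over all species wins.
    Order-free in the dataset rows by construction.
    """
    T = measure_period(traj, "Per2")
    if T is None:
        return FAILED_SIMULATION_COST
    t_rel = traj.times - traj.times[0]
    n_shift = 64
    shifts = np.linspace(0.0, T, n_shift, endpoint=False)
    total = np.zeros(n_shift)
    count = 0
    for sp in dataset.species:
        if sp not in traj.species:
            continue
        x = traj.column(sp)
        xn = x / np.max(x)
        data = np.asarray(dataset.values[sp], dtype=float)
        dn = data / np.max(data)
        for k, s in enumerate(shifts):
            model_vals = np.interp((dataset.times + s) % T, t_rel, xn)
            total[k] += np.sum((model_vals - dn) ** 2)
        count += len(data)
    if count == 0:
        raise ValueError("dataset species do not overlap model species")

    def sse_at(shift: float) -> float:
        acc = 0.0
        for sp in dataset.species:
            if sp not in traj.species:
                continue
            x = traj.column(sp)
            xn = x / np.max(x)
            data = np.asarray(dataset.values[sp], dtype=float)
            dn = data / np.max(data)
            model_vals = np.interp((dataset.times + shift) % T, t_rel, xn)
            acc += np.sum((model_vals - dn) ** 2)
        return acc / count

    # parabolic refinement of the best grid shift (grid step is T/64)
    k = int(np.argmin(total))
    h = T / n_shift
    s0 = shifts[k]
    f_m, f_0, f_p = (sse_at((s0 - h) % T), total[k] / count, sse_at((s0 + h) % T))
    denom = f_m - 2.0 * f_0 + f_p
    delta = 0.5 * (f_m - f_p) / denom * h if denom > 0 else 0.0
    refined = sse_at((s0 + delta) % T)
    return float(min(refined, f_0))


def _oscillates(variant, params, mutant, species) -> bool:
    try:
        traj = simulate(variant, params, mutant, **_FIT_SIM)
    except IntegrationError:
        return False
    return measure_period(traj, species) is not None


def fit_cost(
    params: ParameterSet,
    dataset: TimecourseDataset,
    constraints: FitConstraints,
    variant=ModelVariant.PRE,
    mutant: MutantSpec = WILD_TYPE,
) -> float:
    """Non-negative fit score; 0 only when every term vanishes.

    A failed simulation returns a large finite sentinel cost so stochastic
    samplers can continue past pathological parameter sets.
    """
    try:
        traj = simulate(variant, params, mutant, **_FIT_SIM)
    except IntegrationError:
        logger.warning("fit_cost: simulation failed at %s", params.fingerprint())
        return FAILED_SIMULATION_COST

    cost = 0.0
    if constraints.weight_timecourse > 0:
        sse = _timecourse_sse(traj, dataset)
        if sse >= FAILED_SIMULATION_COST:
            return FAILED_SIMULATION_COST
        cost += constraints.weight_timecourse * sse

    period = measure_period(traj, "Per2")
    if period is None:
        return FAILED_SIMULATION_COST
    cost += constraints.weight_period * _window_penalty(period, constraints.period_window)

    phases = measure_phases(traj, "Per2AS") if "Per2AS" in traj.species else None
    if phases and "Per2" in phases:
        d = abs(phases["Per2"] - phases["Per2AS"]) % period
        dphi = min(d, period - d)
        cost += constraints.weight_phase * _window_penalty(dphi, constraints.phase_diff_window)

    for beh in constraints.mutant_behaviours:
        osc = _oscillates(variant, params, beh.mutant, beh.species)
        if osc != beh.should_oscillate:
            cost += constraints.weight_mutant
    return float(cost)


@dataclass
class EnsembleResult:
    """Accepted parameter sets with costs, plus sampler statistics."""

    accepted: list[tuple[ParameterSet, float]]
    n_steps: int
    n_moves: int                  # Metropolis moves taken
    seed: int
    threshold: float
    final_step_size: float

    @property
    def acceptance_rate(self) -> float:
        return self.n_moves / max(self.n_steps, 1)

    def parameter_frame(self, symbols: Optional[Sequence[str]] = None) -> pd.DataFrame:
        rows = []
        for ps, cost in self.accepted:
            row = ps.as_dict() if symbols is None else {s: ps[s] for s in symbols}
            row["cost"] = cost
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, symbols: Optional[Sequence[str]] = None) -> None:
        self.parameter_frame(symbols).to_csv(path, index=False)


def ensemble_fit(
    dataset: TimecourseDataset,
    constraints: FitConstraints,
    free_params: Sequence[str],
    bounds: dict[str, tuple[float, float]],
    n_steps: int = 1000,
    temperature: float = 0.05,
    seed: int = 0,
    threshold: Optional[float] = None,
    start: Optional[ParameterSet] = None,
    variant=ModelVariant.PRE,
    step_size: float = 0.15,
) -> EnsembleResult:
    """Metropolis random walk in log-parameter space.

    Gaussian proposals in ``log(p)`` with hard reflection at the bounds
    (rate constants span decades, so log space is the natural metric); the
    step size adapts every 50 steps toward a 20–40% acceptance rate.  All
    visited sets with cost below ``threshold`` are collected.  Deterministic
    given ``seed``.
    """
    from .parameters import wt_parameters

    if start is None:
        start = wt_parameters()
    missing = [s for s in free_params if s not in start]
    if missing:
        raise KeyError(f"free parameters not in the parameter set: {missing}")
    for s in free_params:
        lo, hi = bounds[s]
        if not (0 < lo < hi):
            raise ValueError(f"bounds for {s!r} must satisfy 0 < lo < hi")

    rng = np.random.default_rng(seed)
    log_bounds = {s: (np.log(bounds[s][0]), np.log(bounds[s][1])) for s in free_params}
    current = {s: float(np.clip(start[s], *bounds[s])) for s in free_params}
    current_ps = start.replace(name="ensemble-member", **current)
    current_cost = fit_cost(current_ps, dataset, constraints, variant=variant)
    if threshold is None:
        threshold = max(2.0 * current_cost, 1e-6)

    accepted: list[tuple[ParameterSet, float]] = []
    if current_cost <= threshold:
        accepted.append((current_ps, current_cost))

    sigma = step_size
    n_moves = 0
    window_moves = 0
    for step in range(1, n_steps + 1):
        proposal = {}
        for s in free_params:
            z = np.log(current[s]) + rng.normal(0.0, sigma)
            lo, hi = log_bounds[s]
            # hard reflection at the bounds
            span = hi - lo
            z = (z - lo) % (2 * span)
            z = lo + (z if z <= span else 2 * span - z)
            proposal[s] = float(np.exp(z))
        prop_ps = start.replace(name="ensemble-member", **proposal)
        prop_cost = fit_cost(prop_ps, dataset, constraints, variant=variant)
        if prop_cost <= current_cost or (
            temperature > 0
            and rng.random() < np.exp(-(prop_cost - current_cost) / temperature)
        ):
            current, current_ps, current_cost = proposal, prop_ps, prop_cost
            n_moves += 1
            window_moves += 1
            if current_cost <= threshold:
                accepted.append((current_ps, current_cost))
        if step % 50 == 0:
            rate = window_moves / 50.0
            if rate < 0.20:
                sigma *= 0.7
            elif rate > 0.40:
                sigma *= 1.3
            window_moves = 0

    if n_moves == 0:
        raise RuntimeError(
            f"ensemble_fit made no moves in {n_steps} steps "
            f"(start cost {current_cost:.3g}, final step size {sigma:.3g}); "
            "widen bounds or raise the temperature"
        )
    return EnsembleResult(accepted, n_steps, n_moves, seed, float(threshold), float(sigma))
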