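"""Steady states, linear stability, Hopf points and parameter-plane loci.

AUTO-style pseudo-arclength continuation is deliberately replaced by grid
scanning with solution reuse plus bisection refinement: adequate for the
one- and two-parameter diagrams this package produces, and declared as a
limitation for strongly folded branches.  Oscillation envelopes come from
simulation, not Floquet continuation.

Swept quantities may be any :class:`~per2as.parameters.ParameterSet` symbol
or one of the mutant fields ``y4_0`` / ``x5_0``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .antisense import ModelVariant
from .model import MutantSpec, WILD_TYPE, assemble_rhs, initial_state, state_dimension
from .parameters import ParameterSet
from .rhythms import (
    IntegrationError,
    RhythmCriteria,
    classify_circadian_antiphasic,
    measure_period,
    simulate,
    summarize_limit_cycle,
)

__all__ = [
    "SteadyStateRecord",
    "HopfPoint",
    "BranchDiagram",
    "TwoParamLocus",
    "numerical_jacobian",
    "steady_state_of",
    "find_steady_state",
    "scan_rhs_family",
    "scan_parameter",
    "trace_hopf_locus",
    "trace_isoperiod_locus",
    "classify_region_grid",
]

logger = logging.getLogger(__name__)

NEWTON_TOL = 1e-9           # residual < tol * (1 + ||state||)
NEWTON_MAX_ITER = 200
FD_REL_STEP = 1e-6          # central-difference Jacobian step (relative)
HOPF_RE_TOL = 1e-6          # |max Re(lambda)| at a refined Hopf point
ISOPERIOD_TOL = 0.02        # h
COMPLEX_IM_MIN = 1e-4       # rad/h: eigenvalues with |Im| above this count
                            # as a complex pair


def _apply(params: ParameterSet, mutant: MutantSpec, name: str, value: float):
    """Set a swept quantity on (params, mutant) by name."""
    if name == "y4_0":
        return params, dc_replace(mutant, y4_0=float(value))
    if name == "x5_0":
        return params, dc_replace(mutant, x5_0=float(value))
    return params.replace(**{name: float(value)}), mutant


@dataclass(frozen=True)
class SteadyStateRecord:
    """A Newton-refined fixed point with its linearization."""

    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    converged: bool

    @property
    def stable(self) -> bool:
        return bool(np.max(self.eigenvalues.real) < 0.0)

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigenvalues.real))

    @property
    def leading_complex_pair(self) -> Optional[complex]:
        """Complex eigenvalue (Im > 0) with the largest real part."""
        cplx = self.eigenvalues[np.abs(self.eigenvalues.imag) > COMPLEX_IM_MIN]
        if len(cplx) == 0:
            return None
        lead = cplx[np.argmax(cplx.real)]
        return complex(lead.real, abs(lead.imag))


@dataclass(frozen=True)
class HopfPoint:
    """Location of a stability change with its crossing frequency."""

    parameter: str
    value: float
    omega: float               # rad/h

    @property
    def emergent_period(self) -> float:
        """Period 2*pi/omega of the oscillation born at the Hopf point (h)."""
        return 2.0 * np.pi / self.omega


@dataclass
class BranchDiagram:
    """One-parameter scan: steady states, stability, envelopes, Hopf points."""

    parameter: str
    values: np.ndarray
    states: np.ndarray               # (n, dim)
    residuals: np.ndarray
    max_real_parts: np.ndarray
    stable: np.ndarray               # bool
    resolved: np.ndarray             # bool, Newton converged
    envelope_min: np.ndarray         # simulated min of tracked species (NaN if skipped)
    envelope_max: np.ndarray
    period: np.ndarray               # NaN where non-oscillatory
    hopf_points: list[HopfPoint] = field(default_factory=list)
    tracked_species: str = "Per2"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.parameter: self.values,
            "steady_" + self.tracked_species: self.states[:, 0],
            "residual": self.residuals,
            "max_re_eig": self.max_real_parts,
            "stable": self.stable,
            "resolved": self.resolved,
            "env_min": self.envelope_min,
            "env_max": self.envelope_max,
            "period_h": self.period,
        })

    def to_csv(self, path, sidecar: Optional[dict] = None) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = dict(
            parameter=self.parameter,
            tracked_species=self.tracked_species,
            hopf_points=[
                dict(parameter=h.parameter, value=h.value, omega=h.omega,
                     emergent_period=h.emergent_period)
                for h in self.hopf_points
            ],
        )
        if sidecar:
            meta.update(sidecar)
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)


@dataclass
class TwoParamLocus:
    """Ordered points of a locus in a two-parameter plane."""

    kind: str                       # "hopf" | "iso-period" | "region-boundary"
    p1_name: str
    p2_name: str
    points: list[tuple[float, float]]
    target: Optional[float] = None  # e.g. iso-period T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=[self.p1_name, self.p2_name])

    def to_csv(self, path, sidecar: Optional[dict] = None) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = dict(kind=self.kind, p1=self.p1_name, p2=self.p2_name,
                    target=self.target)
        if sidecar:
            meta.update(sidecar)
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# Newton / Jacobian
# ---------------------------------------------------------------------------

def numerical_jacobian(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian with relative step 1e-6."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        h = FD_REL_STEP * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (f(xp) - f(xm)) / (2.0 * h)
    return J


def _newton(f: Callable[[np.ndarray], np.ndarray], x0: np.ndarray):
    """Damped Newton iteration; returns (x, residual_norm, converged)."""
    x = np.asarray(x0, dtype=float).copy()
    fx = f(x)
    res = np.linalg.norm(fx)
    for _ in range(NEWTON_MAX_ITER):
        if res < NEWTON_TOL * (1.0 + np.linalg.norm(x)):
            return x, res, True
        J = numerical_jacobian(f, x)
        try:
            step = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError:
            return x, res, False
        lam = 1.0
        for _ in range(40):
            x_new = x + lam * step
            fx_new = f(x_new)
            res_new = np.linalg.norm(fx_new)
            if res_new < res:
                break
            lam *= 0.5
        else:
            return x, res, False
        x, fx, res = x_new, fx_new, res_new
    converged = res < NEWTON_TOL * (1.0 + np.linalg.norm(x))
    return x, res, converged


def steady_state_of(f: Callable[[np.ndarray], np.ndarray], guess) -> SteadyStateRecord:
    """Newton fixed point of an arbitrary autonomous RHS ``f(x) -> dx/dt``."""
    x, res, converged = _newton(f, np.asarray(guess, dtype=float))
    eigs = np.linalg.eigvals(numerical_jacobian(f, x))
    return SteadyStateRecord(x, float(res), eigs, bool(converged))


def find_steady_state(
    variant,
    params: ParameterSet,
    mutant: MutantSpec = WILD_TYPE,
    guess: Optional[np.ndarray] = None,
) -> SteadyStateRecord:
    """Damped-Newton fixed point of the RHS, with spectrum and stability.

    The default guess is the endpoint of a 1000 h integration (robust in
    stable regimes and a good seed for unstable ones).
    """
    variant = ModelVariant.coerce(variant)
    rhs = assemble_rhs(variant, params, mutant)
    if mutant.x5_0 is not None:
        # the clamp zeroes the REV_n derivative, which would make the Newton
        # Jacobian singular; replace that row by the algebraic constraint
        # REV_n = x5_0 (contributing a harmless -1 eigenvalue)
        from .model import CORE_SPECIES

        i_rev = CORE_SPECIES.index("REV_n")
        x5_0 = mutant.x5_0

        def f(x):
            d = rhs(0.0, x)
            d[i_rev] = x5_0 - x[i_rev]
            return d
    else:
        f = lambda x: rhs(0.0, x)
    if guess is None:
        traj = simulate(variant, params, mutant, t_end=1000.0, transient=990.0, dt=1.0)
        guess = traj.states[-1]
    rec = steady_state_of(f, guess)
    if not rec.converged:
        # restart from a long integration endpoint
        traj = simulate(variant, params, mutant, t_end=2000.0, transient=1990.0, dt=1.0)
        rec = steady_state_of(f, traj.states[-1])
    return rec


# ---------------------------------------------------------------------------
# one-parameter scan
# ---------------------------------------------------------------------------

def _max_re_at(variant, params, mutant, name, value, guess):
    """(max Re eig, record) of the steady state at a swept-parameter value."""
    p, m = _apply(params, mutant, name, value)
    rec = find_steady_state(variant, p, m, guess=guess)
    return rec.max_real_part, rec


def _bisect_hopf_generic(steady_at, name, lo, hi, rec_lo, rec_hi) -> Optional[HopfPoint]:
    """Bisection of max Re(lambda); ``steady_at(value, guess)`` -> record."""
    f_lo = rec_lo.max_real_part
    x_lo, x_hi = lo, hi
    guess = rec_lo.state
    rec_mid = rec_lo
    for _ in range(60):
        mid = 0.5 * (x_lo + x_hi)
        rec_mid = steady_at(mid, guess)
        f_mid = rec_mid.max_real_part
        if not rec_mid.converged:
            logger.warning("Hopf bisection: unresolved point at %s=%g", name, mid)
            return None
        guess = rec_mid.state
        if abs(f_mid) < HOPF_RE_TOL:
            break
        if np.sign(f_mid) == np.sign(f_lo):
            x_lo, f_lo = mid, f_mid
        else:
            x_hi = mid
    pair = rec_mid.leading_complex_pair
    if pair is None:
        logger.warning("stability change at %s=%g has no complex pair "
                       "(not a Hopf point)", name, 0.5 * (x_lo + x_hi))
        return None
    return HopfPoint(name, float(0.5 * (x_lo + x_hi)), float(pair.imag))


def _bisect_hopf(variant, params, mutant, name, lo, hi, rec_lo, rec_hi) -> Optional[HopfPoint]:
    """Bisection of max Re(lambda) between bracketing grid points."""
    f_lo = rec_lo.max_real_part
    f_hi = rec_hi.max_real_part
    x_lo, x_hi = lo, hi
    guess = rec_lo.state
    rec_mid = rec_lo
    for _ in range(60):
        mid = 0.5 * (x_lo + x_hi)
        f_mid, rec_mid = _max_re_at(variant, params, mutant, name, mid, guess)
        if not rec_mid.converged:
            logger.warning("Hopf bisection: unresolved point at %s=%g", name, mid)
            return None
        guess = rec_mid.state
        if abs(f_mid) < HOPF_RE_TOL:
            break
        if np.sign(f_mid) == np.sign(f_lo):
            x_lo, f_lo = mid, f_mid
        else:
            x_hi, f_hi = mid, f_mid
    pair = rec_mid.leading_complex_pair
    if pair is None:
        logger.warning("stability change at %s=%g has no complex pair "
                       "(not a Hopf point)", name, 0.5 * (x_lo + x_hi))
        return None
    return HopfPoint(name, float(0.5 * (x_lo + x_hi)), float(pair.imag))


def scan_parameter(
    variant,
    param_name: str,
    lo: float,
    hi: float,
    n_points: int = 101,
    params: Optional[ParameterSet] = None,
    mutant: MutantSpec = WILD_TYPE,
    tracked_species: str = "Per2",
    compute_envelopes: bool = True,
    simulate_kwargs: Optional[dict] = None,
) -> BranchDiagram:
    """One-parameter branch diagram with Hopf points refined by bisection.

    Steady states are continued across the grid by reusing the previous
    solution as the Newton guess; unresolved points are logged and skipped.
    Envelopes and periods come from simulation at each grid point.
    """
    from .parameters import wt_parameters

    if n_points < 20:
        raise ValueError("n_points must be >= 20 for a meaningful scan")
    if params is None:
        params = wt_parameters()
    variant = ModelVariant.coerce(variant)
    values = np.linspace(lo, hi, n_points)
    dim = state_dimension(variant)
    states = np.full((n_points, dim), np.nan)
    residuals = np.full(n_points, np.nan)
    max_re = np.full(n_points, np.nan)
    stable = np.zeros(n_points, dtype=bool)
    resolved = np.zeros(n_points, dtype=bool)
    env_min = np.full(n_points, np.nan)
    env_max = np.full(n_points, np.nan)
    period = np.full(n_points, np.nan)
    sim_kw = dict(t_end=1100.0, transient=850.0, dt=0.1)
    if simulate_kwargs:
        sim_kw.update(simulate_kwargs)

    records: list[Optional[SteadyStateRecord]] = [None] * n_points
    guess = None
    for i, v in enumerate(values):
        p, m = _apply(params, mutant, param_name, v)
        try:
            rec = find_steady_state(variant, p, m, guess=guess)
        except IntegrationError as err:
            logger.warning("scan point %s=%g failed: %s", param_name, v, err)
            continue
        records[i] = rec
        if rec.converged:
            guess = rec.state
            states[i] = rec.state
            residuals[i] = rec.residual
            max_re[i] = rec.max_real_part
            stable[i] = rec.stable
            resolved[i] = True
        if compute_envelopes:
            try:
                traj = simulate(variant, p, m, **sim_kw)
            except IntegrationError as err:
                logger.warning("envelope at %s=%g failed: %s", param_name, v, err)
                continue
            x = traj.column(tracked_species)
            env_min[i] = float(np.min(x))
            env_max[i] = float(np.max(x))
            T = measure_period(traj, tracked_species)
            if T is not None:
                period[i] = T

    hopf: list[HopfPoint] = []
    for i in range(n_points - 1):
        r1, r2 = records[i], records[i + 1]
        if r1 is None or r2 is None or not (r1.converged and r2.converged):
            continue
        if np.sign(r1.max_real_part) != np.sign(r2.max_real_part):
            hp = _bisect_hopf(variant, params, mutant, param_name,
                              values[i], values[i + 1], r1, r2)
            if hp is not None:
                hopf.append(hp)

    idx = states[:, 0]  # noqa: F841  (kept for debugging)
    return BranchDiagram(param_name, values, states, residuals, max_re,
                         stable, resolved, env_min, env_max, period,
                         hopf, tracked_species)


def scan_rhs_family(
    rhs_factory: Callable[[float], Callable[[np.ndarray], np.ndarray]],
    param_name: str,
    lo: float,
    hi: float,
    n_points: int,
    guess0: np.ndarray,
) -> list[HopfPoint]:
    """Hopf points of an arbitrary parameterized RHS family on a grid.

    Steady states are continued with solution reuse; each stability change
    with a complex leading pair is refined by bisection.  Used for analytic
    oracle systems (e.g. the Hopf normal form) and custom models.
    """
    def steady_at(value, guess):
        return steady_state_of(rhs_factory(value), guess)

    values = np.linspace(lo, hi, n_points)
    records = []
    guess = np.asarray(guess0, dtype=float)
    for v in values:
        rec = steady_at(v, guess)
        records.append(rec)
        if rec.converged:
            guess = rec.state
    hopf = []
    for i in range(n_points - 1):
        r1, r2 = records[i], records[i + 1]
        if not (r1.converged and r2.converged):
            continue
        if np.sign(r1.max_real_part) != np.sign(r2.max_real_part):
            hp = _bisect_hopf_generic(steady_at, param_name,
                                      values[i], values[i + 1], r1, r2)
            if hp is not None:
                hopf.append(hp)
    return hopf


# ---------------------------------------------------------------------------
# two-parameter loci
# ---------------------------------------------------------------------------

def trace_hopf_locus(
    variant,
    p1_name: str,
    p1_range: tuple[float, float],
    p2_name: str,
    p2_values: Sequence[float],
    seed_hopf: HopfPoint,
    params: Optional[ParameterSet] = None,
    mutant: MutantSpec = WILD_TYPE,
) -> TwoParamLocus:
    """March ``p2`` over a grid, re-bisecting the Hopf condition in ``p1``.

    At each ``p2`` the bracket in ``p1`` is centered on the previous locus
    point; the locus is truncated (with a log message) when no sign change
    can be bracketed.
    """
    from .parameters import wt_parameters

    if params is None:
        params = wt_parameters()
    variant = ModelVariant.coerce(variant)
    lo, hi = p1_range
    width = (hi - lo) / 8.0
    p1_current = seed_hopf.value
    points: list[tuple[float, float]] = []
    for p2 in p2_values:
        p_base, m_base = _apply(params, mutant, p2_name, p2)
        found = False
        for grow in (1.0, 2.0, 4.0):
            b_lo = max(lo, p1_current - grow * width)
            b_hi = min(hi, p1_current + grow * width)
            try:
                f_lo, r_lo = _max_re_at(variant, p_base, m_base, p1_name, b_lo, None)
                f_hi, r_hi = _max_re_at(variant, p_base, m_base, p1_name, b_hi, r_lo.state)
            except IntegrationError:
                break
            if not (r_lo.converged and r_hi.converged):
                break
            if np.sign(f_lo) != np.sign(f_hi):
                hp = _bisect_hopf(variant, p_base, m_base, p1_name,
                                  b_lo, b_hi, r_lo, r_hi)
                if hp is not None:
                    points.append((hp.value, float(p2)))
                    p1_current = hp.value
                    found = True
                break
        if not found:
            logger.info("Hopf locus lost bracket at %s=%g; truncating", p2_name, p2)
            break
    return TwoParamLocus("hopf", p1_name, p2_name, points)


def _measured_period(variant, params, mutant, species, sim_kw) -> Optional[float]:
    try:
        traj = simulate(variant, params, mutant, **sim_kw)
    except IntegrationError:
        return None
    return measure_period(traj, species)


def trace_isoperiod_locus(
    variant,
    p1_name: str,
    p1_values: Sequence[float],
    p2_name: str,
    p2_range: tuple[float, float],
    T_target: float,
    n_coarse: int = 9,
    params: Optional[ParameterSet] = None,
    mutant: MutantSpec = WILD_TYPE,
    species: str = "Per2",
    simulate_kwargs: Optional[dict] = None,
) -> TwoParamLocus:
    """Iso-period locus: points where the simulated period equals ``T_target``.

    For each ``p1`` the period is sampled on a coarse ``p2`` grid; every sign
    change of ``period - T_target`` between oscillatory neighbours is refined
    by bisection in ``p2`` to 0.02 h.  Multiple roots per ``p1`` are all
    reported; a ``p1`` with no bracket contributes no points.
    """
    from .parameters import wt_parameters

    if params is None:
        params = wt_parameters()
    variant = ModelVariant.coerce(variant)
    sim_kw = dict(t_end=1100.0, transient=850.0, dt=0.1)
    if simulate_kwargs:
        sim_kw.update(simulate_kwargs)
    lo, hi = p2_range
    coarse = np.linspace(lo, hi, n_coarse)
    points: list[tuple[float, float]] = []
    for p1 in p1_values:
        p_base, m_base = _apply(params, mutant, p1_name, p1)

        def err(p2v: float) -> Optional[float]:
            p, m = _apply(p_base, m_base, p2_name, p2v)
            T = _measured_period(variant, p, m, species, sim_kw)
            return None if T is None else T - T_target

        errs = [err(v) for v in coarse]
        for i in range(n_coarse - 1):
            e1, e2 = errs[i], errs[i + 1]
            if e1 is None or e2 is None or np.sign(e1) == np.sign(e2):
                continue
            a, b, ea = coarse[i], coarse[i + 1], e1
            for _ in range(40):
                if b - a < 1e-6:
                    break
                mid = 0.5 * (a + b)
                em = err(mid)
                if em is None:
                    break
                if abs(em) < ISOPERIOD_TOL:
                    a = b = mid
                    break
                if np.sign(em) == np.sign(ea):
                    a, ea = mid, em
                else:
                    b = mid
            points.append((float(p1), float(0.5 * (a + b))))
    return TwoParamLocus("iso-period", p1_name, p2_name, points, target=T_target)


def classify_region_grid(
    variant,
    p1_name: str,
    p1_values: Sequence[float],
    p2_name: str,
    p2_values: Sequence[float],
    criteria: RhythmCriteria,
    params: Optional[ParameterSet] = None,
    mutant: MutantSpec = WILD_TYPE,
    simulate_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Simulate and classify every grid cell of a two-parameter plane.

    Returns a DataFrame with one row per cell and a ``classification``
    column: ``non-oscillatory``, ``oscillatory``, ``circadian`` (period
    inside the criteria band) or ``circadian-antiphasic`` (all criteria).
    Failed cells are marked ``failed`` rather than aborting the grid.
    """
    from .parameters import wt_parameters

    if params is None:
        params = wt_parameters()
    if len(p1_values) * len(p2_values) > 10_000:
        raise ValueError("grid exceeds 10^4 cells")
    variant = ModelVariant.coerce(variant)
    sim_kw = dict(t_end=1100.0, transient=850.0, dt=0.1)
    if simulate_kwargs:
        sim_kw.update(simulate_kwargs)
    rows = []
    for p1 in p1_values:
        for p2 in p2_values:
            p, m = _apply(*_apply(params, mutant, p1_name, p1), p2_name, p2)
            row = {p1_name: float(p1), p2_name: float(p2), "period_h": np.nan,
                   "amplitude": np.nan, "phase_diff_h": np.nan}
            try:
                traj = simulate(variant, p, m, **sim_kw)
            except IntegrationError:
                row["classification"] = "failed"
                rows.append(row)
                continue
            summary = summarize_limit_cycle(traj)
            if not summary.oscillatory:
                row["classification"] = "non-oscillatory"
                rows.append(row)
                continue
            row["period_h"] = summary.period
            row["amplitude"] = summary.amplitude(criteria.amplitude_species)
            s1, s2 = criteria.phase_pair
            if s1 in summary.phases and s2 in summary.phases:
                row["phase_diff_h"] = summary.phase_difference(s1, s2)
            if classify_circadian_antiphasic(summary, criteria):
                row["classification"] = "circadian-antiphasic"
            elif criteria.period_min < summary.period < criteria.period_max:
                row["classification"] = "circadian"
            else:
                row["classification"] = "oscillatory"
            rows.append(row)
    return pd.DataFrame(rows)
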