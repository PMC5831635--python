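"""The core mammalian circadian clock ODE system and its antisense extensions.

The core model is a two-loop transcription–translation network of 19 species:
five clock-gene mRNAs (*Per2*, *Cry*, *Rev-Erb*, *Ror*, *Bmal1*) and fourteen
proteins/complexes.  CLOCK/BMAL1 activates the clock genes; nuclear PER/CRY
complexes (phosphorylated and unphosphorylated) repress that activation;
nuclear REV-ERB represses and nuclear ROR activates *Bmal1* transcription,
closing the second loop.  The antisense extensions append the *Per2AS*
transcript (and, in the post-transcriptional variant, the Per2:Per2AS duplex)
as extra state variables.

Species ordering is fixed so trajectory columns are stable::

    index  0..4   Per2, Cry, Rev, Ror, Bmal1            (mRNAs y1..y5)
    index  5..18  PER_c, CRY_c, PERp_c, REV_c, REV_n,   (proteins x1..x14;
                  ROR_c, ROR_n, BMAL_c, BMAL_n,          REV_n is x5, the
                  CLK_BMAL, PC_c, PCp_c, PC_n, PCp_n     species clamped by
                                                         the x5^0 mutant)
    index  19     Per2AS   (pre, post, combined variants)
    index  20     Dplx     (post variant only)

Units: hours; concentrations are dimensionless (arbitrary units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

from .antisense import ModelVariant, required_symbols
from .parameters import CORE_SYMBOLS, ParameterSet

__all__ = [
    "CORE_SPECIES",
    "species_names",
    "state_dimension",
    "MutantSpec",
    "regulation_R",
    "core_rhs",
    "assemble_rhs",
    "DEFAULT_INITIAL_STATE",
    "initial_state",
]

#: The 19 core species, in fixed order (mRNAs y1..y5, then proteins x1..x14).
CORE_SPECIES: tuple[str, ...] = (
    "Per2", "Cry", "Rev", "Ror", "Bmal1",
    "PER_c", "CRY_c", "PERp_c", "REV_c", "REV_n",
    "ROR_c", "ROR_n", "BMAL_c", "BMAL_n", "CLK_BMAL",
    "PC_c", "PCp_c", "PC_n", "PCp_n",
)

#: Genes whose dosage (V*max) a MutantSpec may rescale.
_DOSAGE_GENES: dict[str, str] = {
    "Per2": "V1max", "Cry": "V2max", "Rev": "V3max",
    "Ror": "V4max", "Bmal1": "V5max",
}

_IDX = {name: i for i, name in enumerate(CORE_SPECIES)}
_I_REVN = _IDX["REV_n"]          # the "x5" slot targeted by the x5_0 clamp


def species_names(variant) -> tuple[str, ...]:
    """Ordered species names for a model variant."""
    variant = ModelVariant.coerce(variant)
    if variant is ModelVariant.RELOGIO:
        return CORE_SPECIES
    if variant is ModelVariant.POST:
        return CORE_SPECIES + ("Per2AS", "Dplx")
    return CORE_SPECIES + ("Per2AS",)


def state_dimension(variant) -> int:
    return len(species_names(variant))


@dataclass(frozen=True)
class MutantSpec:
    """Genetic perturbations of the core clock.

    Attributes
    ----------
    y4_0
        Constant exogenous *Ror* transcription rate (e.g. from a plasmid),
        added to the *Ror* mRNA equation.  ``0`` is wild type.
    x5_0
        If set, nuclear REV-ERB is clamped at this constant level: the
        constant is substituted into every term referencing REV_n and the
        REV_n derivative is zeroed (the variable is kept so the state
        dimension is uniform across mutants).
    dosage
        Per-gene multipliers applied to the corresponding V*max
        (knock-out: 0; over-expression: > 1).  Genes: Per2, Cry, Rev, Ror,
        Bmal1.
    """

    y4_0: float = 0.0
    x5_0: Optional[float] = None
    dosage: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.y4_0 < 0:
            raise ValueError("y4_0 must be >= 0")
        if self.x5_0 is not None and self.x5_0 < 0:
            raise ValueError("x5_0 must be >= 0")
        for gene, mult in self.dosage.items():
            if gene not in _DOSAGE_GENES:
                raise KeyError(f"unknown gene for dosage multiplier: {gene!r}")
            if mult < 0:
                raise ValueError(f"dosage multiplier for {gene} must be >= 0")

    def is_wild_type(self) -> bool:
        return (
            self.y4_0 == 0.0
            and self.x5_0 is None
            and all(m == 1.0 for m in self.dosage.values())
        )


WILD_TYPE = MutantSpec()


def regulation_R(clk_bmal: float, per_cry_nuclear: float, params: ParameterSet) -> float:
    """Hill-type gene-regulation function for *Per2* transcription.

    ``R = [(1/a) + (x/Kt1)^b] / [1 + (x/Kt1)^b * (1 + (y/Ki1)^c)]`` with
    ``x`` the CLOCK/BMAL1 activator and ``y`` total nuclear PER/CRY
    repressor.  Strictly positive and bounded by 1; the basal value at
    ``x = 0`` is ``1/a``.
    """
    if not (math.isfinite(clk_bmal) and math.isfinite(per_cry_nuclear)):
        raise ValueError("non-finite input to regulation_R")
    if clk_bmal < 0 or per_cry_nuclear < 0:
        raise ValueError("regulation_R inputs must be >= 0")
    Kt1, Ki1 = params["Kt1"], params["Ki1"]
    if Kt1 == 0:
        raise ValueError("Kt1 must be > 0")
    if Ki1 == 0:
        raise ValueError("Ki1 must be > 0")
    act = (clk_bmal / Kt1) ** params["b"]
    rep = (per_cry_nuclear / Ki1) ** params["c"]
    return (1.0 / params["a"] + act) / (1.0 + act * (1.0 + rep))


def _effective_core_constants(params: ParameterSet, mutant: MutantSpec) -> dict[str, float]:
    params.require(*CORE_SYMBOLS)
    eff = {k: params[k] for k in CORE_SYMBOLS}
    for gene, mult in mutant.dosage.items():
        eff[_DOSAGE_GENES[gene]] *= mult
    return eff


def _make_core_rhs(
    params: ParameterSet, mutant: MutantSpec
) -> Callable[[np.ndarray, np.ndarray], None]:
    """Build a function writing the 19 core derivatives into ``out[:19]``.

    Returns a closure over plain floats; clamping of REV_n (x5^0 mutant) is
    applied by substituting the constant into every referencing term and
    zeroing the REV_n derivative.
    """
    p = _effective_core_constants(params, mutant)
    (V1, V2, V3, V4, V5) = (p["V1max"], p["V2max"], p["V3max"], p["V4max"], p["V5max"])
    (a1, a2, a3, a4, a5) = (p["a"], p["a2"], p["a3"], p["a4"], p["a5"])
    (b1, c1, b2, c2, b3, c3, b4, c4, b5, c5) = (
        p["b"], p["c"], p["b2"], p["c2"], p["b3"], p["c3"],
        p["b4"], p["c4"], p["b5"], p["c5"],
    )
    (Kt1, Kt2, Kt3, Kt4, Kt5) = (p["Kt1"], p["Kt2"], p["Kt3"], p["Kt4"], p["Kt5"])
    (Ki1, Ki2, Ki3, Ki4, Ki5) = (p["Ki1"], p["Ki2"], p["Ki3"], p["Ki4"], p["Ki5"])
    Ki6, c6 = p["Ki6"], p["c6"]
    (dy1, dy2, dy3, dy4, dy5) = (p["d_y1"], p["d_y2"], p["d_y3"], p["d_y4"], p["d_y5"])
    (kp1, kp2, kp3, kp4, kp5) = (p["k_p1"], p["k_p2"], p["k_p3"], p["k_p4"], p["k_p5"])
    kph, kdph = p["k_ph"], p["k_dph"]
    kf1, kd1, kf2, kd2 = p["k_f1"], p["k_d1"], p["k_f2"], p["k_d2"]
    kim1, kex1, kim2, kex2 = p["k_im1"], p["k_ex1"], p["k_im2"], p["k_ex2"]
    kim3, kim4, kim5 = p["k_im3"], p["k_im4"], p["k_im5"]
    kact, kdeact = p["k_act"], p["k_deact"]
    dx = [p[f"d_x{i}"] for i in range(1, 15)]

    y4_0 = mutant.y4_0
    x5_clamp = mutant.x5_0

    def core(y: np.ndarray, out: np.ndarray) -> None:
        (per2, cry, rev, ror, bmal,
         PERc, CRYc, PERpc, REVc, REVn,
         RORc, RORn, BMALc, BMALn, CB,
         PCc, PCpc, PCn, PCpn) = y[:19]

        if x5_clamp is not None:
            REVn = x5_clamp
        # adaptive solvers may probe marginally negative states; Hill terms
        # with non-integer exponents need the inputs clipped at zero
        CB = CB if CB > 0.0 else 0.0
        REVn = REVn if REVn > 0.0 else 0.0
        RORn_h = RORn if RORn > 0.0 else 0.0
        pcn_tot = PCn + PCpn
        if pcn_tot < 0.0:
            pcn_tot = 0.0

        # transcription (clock genes activated by CLOCK/BMAL, repressed by
        # nuclear PER/CRY; Bmal1 activated by ROR_n, repressed by REV_n)
        act1 = (CB / Kt1) ** b1
        act2 = (CB / Kt2) ** b2
        act3 = (CB / Kt3) ** b3
        act4 = (CB / Kt4) ** b4
        rep1 = (pcn_tot / Ki1) ** c1
        rep2 = (pcn_tot / Ki2) ** c2
        rep3 = (pcn_tot / Ki3) ** c3
        rep4 = (pcn_tot / Ki4) ** c4
        tx_per2 = a1 * V1 * (1.0 / a1 + act1) / (1.0 + act1 * (1.0 + rep1))
        # Cry transcription carries an extra REV-ERB repression factor
        tx_cry = (a2 * V2 * (1.0 / a2 + act2) / (1.0 + act2 * (1.0 + rep2))
                  / (1.0 + (REVn / Ki6) ** c6))
        tx_rev = a3 * V3 * (1.0 / a3 + act3) / (1.0 + act3 * (1.0 + rep3))
        tx_ror = a4 * V4 * (1.0 / a4 + act4) / (1.0 + act4 * (1.0 + rep4))
        act5 = (RORn_h / Kt5) ** b5
        rep5 = (REVn / Ki5) ** c5
        tx_bmal = a5 * V5 * (1.0 / a5 + act5) / (1.0 + act5 + rep5)

        out[0] = tx_per2 - dy1 * per2
        out[1] = tx_cry - dy2 * cry
        out[2] = tx_rev - dy3 * rev
        out[3] = tx_ror - dy4 * ror + y4_0
        out[4] = tx_bmal - dy5 * bmal

        # PER phosphorylation cycle and PER/CRY complex formation
        bind1 = kf1 * PERc * CRYc
        bind2 = kf2 * PERpc * CRYc
        out[5] = kp1 * per2 - kph * PERc + kdph * PERpc - bind1 + kd1 * PCc - dx[0] * PERc
        out[6] = kp2 * cry - bind1 - bind2 + kd1 * PCc + kd2 * PCpc - dx[1] * CRYc
        out[7] = kph * PERc - kdph * PERpc - bind2 + kd2 * PCpc - dx[2] * PERpc

        # REV-ERB and ROR shuttling
        out[8] = kp3 * rev - kim3 * REVc - dx[3] * REVc
        out[9] = 0.0 if x5_clamp is not None else kim3 * REVc - dx[4] * REVn
        out[10] = kp4 * ror - kim4 * RORc - dx[5] * RORc
        out[11] = kim4 * RORc - dx[6] * RORn

        # BMAL shuttling and CLOCK/BMAL activation
        out[12] = kp5 * bmal - kim5 * BMALc - dx[7] * BMALc
        out[13] = kim5 * BMALc - kact * BMALn + kdeact * CB - dx[8] * BMALn
        out[14] = kact * BMALn - kdeact * CB - dx[9] * CB

        # PER/CRY complexes, cytoplasmic and nuclear
        out[15] = bind1 - kd1 * PCc - kim1 * PCc + kex1 * PCn - dx[10] * PCc
        out[16] = bind2 - kd2 * PCpc - kim2 * PCpc + kex2 * PCpn - dx[11] * PCpc
        out[17] = kim1 * PCc - kex1 * PCn - dx[12] * PCn
        out[18] = kim2 * PCpc - kex2 * PCpn - dx[13] * PCpn

    return core


def core_rhs(
    state: np.ndarray,
    params: ParameterSet,
    mutant: MutantSpec = WILD_TYPE,
) -> np.ndarray:
    """Derivatives of the 19-species core clock at ``state`` (conc/hour)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (19,):
        raise ValueError(f"core state must have shape (19,), got {state.shape}")
    out = np.empty(19)
    _make_core_rhs(params, mutant)(state, out)
    return out


def assemble_rhs(
    variant,
    params: ParameterSet,
    mutant: MutantSpec = WILD_TYPE,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the autonomous right-hand side ``f(t, y) -> dy/dt`` for a variant.

    State dimension: 19 (relogio), 20 (pre, combined: + Per2AS) or
    21 (post: + Per2AS, + Dplx).  Missing extension parameters raise
    ``KeyError`` naming the absent symbols.
    """
    variant = ModelVariant.coerce(variant)
    params.require(*required_symbols(variant))
    core = _make_core_rhs(params, mutant)
    dim = state_dimension(variant)

    if variant is ModelVariant.RELOGIO:

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            out = np.empty(19)
            core(y, out)
            return out

    elif variant is ModelVariant.PRE:
        lam, K_S = params["lam"], params["K_S"]
        mu, K_AS, d_AS = params["mu"], params["K_AS"], params["d_AS"]
        if K_S == 0 or K_AS == 0:
            raise ValueError("K_S and K_AS must be > 0 in the pre variant")
        dy1 = params["d_y1"]

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            out = np.empty(20)
            core(y, out)
            per2, per2as = y[0], y[19]
            p2 = per2 if per2 > 0.0 else 0.0
            p2as = per2as if per2as > 0.0 else 0.0
            tx = out[0] + dy1 * per2  # recover the transcription flux
            out[0] = tx * mu * K_AS / (K_AS + p2as) - dy1 * per2
            out[19] = lam * K_S / (K_S + p2) - d_AS * per2as
            return out

    elif variant is ModelVariant.POST:
        lam0, d_AS = params["lam0"], params["d_AS"]
        k_assn, k_diss, d_dup = params["k_assn"], params["k_diss"], params["d_dup"]

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            out = np.empty(21)
            core(y, out)
            per2, per2as, dplx = y[0], y[19], y[20]
            assn = k_assn * per2as * per2
            diss = k_diss * dplx
            out[0] += -assn + diss
            out[19] = lam0 - assn + diss - d_AS * per2as
            out[20] = assn - diss - d_dup * dplx
            return out

    else:  # combined
        lam0, lam1, K_S = params["lam0"], params["lam1"], params["K_S"]
        mu, K_AS, d_AS = params["mu"], params["K_AS"], params["d_AS"]
        k_assn = params["k_assn"]
        if K_S == 0 or K_AS == 0:
            raise ValueError("K_S and K_AS must be > 0 in the combined variant")
        dy1 = params["d_y1"]

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            out = np.empty(20)
            core(y, out)
            per2, per2as = y[0], y[19]
            p2 = per2 if per2 > 0.0 else 0.0
            p2as = per2as if per2as > 0.0 else 0.0
            assn = k_assn * per2as * per2
            tx = out[0] + dy1 * per2
            out[0] = tx * mu * K_AS / (K_AS + p2as) - assn - dy1 * per2
            out[19] = lam0 + lam1 * K_S / (K_S + p2) - assn - d_AS * per2as
            return out

    rhs.variant = variant        # type: ignore[attr-defined]
    rhs.dimension = dim          # type: ignore[attr-defined]
    return rhs


#: Documented default initial state for the 19 core species (arbitrary
#: positive values; attractors are reached after the transient is discarded).
DEFAULT_INITIAL_STATE: np.ndarray = np.full(19, 1.0)


def initial_state(variant) -> np.ndarray:
    """Default initial state for a variant (extensions start at 0)."""
    dim = state_dimension(variant)
    y0 = np.zeros(dim)
    y0[:19] = DEFAULT_INITIAL_STATE
    return y0
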