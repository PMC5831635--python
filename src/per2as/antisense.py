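"""Sense–antisense interaction mechanisms between Per2 mRNA and Per2AS RNA.

Three mechanisms are implemented as extension terms composable with the core
clock model:

pre-transcriptional
    Mutual transcriptional interference.  Per2AS synthesis is repressed by
    Per2 (``lam * K_S / (K_S + Per2)``) and Per2 transcription is scaled by
    ``mu * K_AS / (K_AS + Per2AS)``.

post-transcriptional
    Mature transcripts hybridize into a double-stranded duplex (``Dplx``)
    with mass-action association ``k_assn``, dissociation ``k_diss`` and
    duplex degradation ``d_dup``; Per2AS is synthesized at the constant
    rate ``lam0``.

combined
    Transcriptional interference plus *irreversible* duplex loss: both
    single strands are consumed at rate ``k_assn * Per2AS * Per2`` and no
    duplex species is tracked (the duplex is assumed to be degraded as fast
    as it forms).
"""

from __future__ import annotations

import enum
import math

from .parameters import ParameterSet

__all__ = [
    "ModelVariant",
    "antisense_production_pre",
    "sense_interference_factor",
    "duplex_fluxes",
    "combined_rhs_terms",
    "required_symbols",
]


class ModelVariant(str, enum.Enum):
    """The four model variants: the unmodified core clock plus three
    antisense-coupled extensions."""

    RELOGIO = "relogio"
    PRE = "pre"
    POST = "post"
    COMBINED = "combined"

    @classmethod
    def coerce(cls, value) -> "ModelVariant":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


#: Extension symbols each variant requires beyond the core table.
_VARIANT_SYMBOLS: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.RELOGIO: (),
    ModelVariant.PRE: ("lam", "mu", "K_S", "K_AS", "d_AS"),
    ModelVariant.POST: ("lam0", "k_assn", "k_diss", "d_dup", "d_AS"),
    ModelVariant.COMBINED: ("lam0", "lam1", "mu", "K_S", "K_AS", "k_assn", "d_AS"),
}


def required_symbols(variant) -> tuple[str, ...]:
    """Extension parameter symbols the given variant requires."""
    return _VARIANT_SYMBOLS[ModelVariant.coerce(variant)]


def _check_finite(**named: float) -> None:
    for key, val in named.items():
        if not math.isfinite(val):
            raise ValueError(f"non-finite input: {key} = {val!r}")


def antisense_production_pre(per2: float, params: ParameterSet) -> float:
    """Per2AS synthesis rate under transcriptional interference.

    Returns ``lam * K_S / (K_S + per2)``: the maximal rate ``lam`` reduced by
    interference from the sense transcript, with half-inhibition at
    ``per2 == K_S``.  Monotone non-increasing in ``per2``.
    """
    _check_finite(per2=per2)
    K_S = params["K_S"]
    if K_S == 0:
        raise ValueError("K_S must be > 0 in the pre-transcriptional term")
    return params["lam"] * K_S / (K_S + per2)


def sense_interference_factor(per2as: float, params: ParameterSet) -> float:
    """Dimensionless multiplier applied to Per2 transcription.

    Returns ``mu * K_AS / (K_AS + per2as)``, in ``(0, mu]``; it multiplies
    the activated transcription rate ``a * V1max * R(...)`` of Per2.
    """
    _check_finite(per2as=per2as)
    K_AS = params["K_AS"]
    if K_AS == 0:
        raise ValueError("K_AS must be > 0 in the pre-transcriptional term")
    return params["mu"] * K_AS / (K_AS + per2as)


def duplex_fluxes(
    per2: float, per2as: float, dplx: float, params: ParameterSet
) -> tuple[float, float, float]:
    """Mass-action duplex fluxes (association, dissociation, degradation).

    association = ``k_assn * per2as * per2``; dissociation = ``k_diss *
    dplx``; degradation = ``d_dup * dplx``.  The post-transcriptional
    derivatives are assembled from exactly these fluxes: Per2 and Per2AS
    each lose association and gain dissociation, the duplex gains
    association and loses dissociation plus degradation.
    """
    _check_finite(per2=per2, per2as=per2as, dplx=dplx)
    association = params["k_assn"] * per2as * per2
    dissociation = params["k_diss"] * dplx
    degradation = params["d_dup"] * dplx
    return association, dissociation, degradation


def combined_rhs_terms(
    per2: float, per2as: float, params: ParameterSet
) -> tuple[float, float]:
    """Extension terms of the combined (pre + irreversible duplex) model.

    Returns ``(dPer2AS/dt, per2_production_factor)`` where the Per2AS
    derivative is ``lam0 + lam1*K_S/(K_S + per2) - k_assn*per2as*per2 -
    d_AS*per2as`` and the production factor ``mu*K_AS/(K_AS + per2as)``
    multiplies Per2 transcription; the caller additionally subtracts the
    irreversible duplex loss ``k_assn*per2as*per2`` from the Per2 derivative.
    """
    _check_finite(per2=per2, per2as=per2as)
    K_S = params["K_S"]
    if K_S == 0:
        raise ValueError("K_S must be > 0 in the combined model")
    loss = params["k_assn"] * per2as * per2
    d_as = (
        params["lam0"]
        + params["lam1"] * K_S / (K_S + per2)
        - loss
        - params["d_AS"] * per2as
    )
    return d_as, sense_interference_factor(per2as, params)
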