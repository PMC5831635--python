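"""Named rate-constant tables for the core clock model and its antisense extensions.

Parameters follow the conventions of the two-loop mammalian circadian clock
model: time in hours, concentrations in arbitrary units.  A :class:`ParameterSet`
is an immutable named map from parameter symbol to a non-negative real value,
with a provenance label (``"WT"`` for the calibrated wild-type table shipped
with the package).

The wild-type table lives in ``data/wt.params`` (one ``name = value`` pair per
line) and is mirrored, for cross-checking, by an XPPAUT-style ``data/wt.ode``
file read through :func:`parse_ode_parameters`.
"""

from __future__ import annotations

import math
import re
from collections.abc import Mapping
from importlib import resources
from typing import Iterator

__all__ = [
    "ParameterSet",
    "wt_parameters",
    "load_parameter_file",
    "write_parameter_file",
    "parse_ode_parameters",
    "CORE_SYMBOLS",
    "ANTISENSE_SYMBOLS",
]

# Symbols that must be strictly positive (fold activations, gene dosage scale,
# interference strength, Hill exponents).
_STRICTLY_POSITIVE = frozenset(
    ["a", "a2", "a3", "a4", "a5", "V1max",
     "b", "c", "b2", "c2", "b3", "c3", "b4", "c4", "b5", "c5", "c6"]
)

#: Core-clock symbols (transcription, translation, transport, degradation).
CORE_SYMBOLS: tuple[str, ...] = (
    # gene dosage scales
    "V1max", "V2max", "V3max", "V4max", "V5max",
    # fold activations
    "a", "a2", "a3", "a4", "a5",
    # Hill exponents (activation b*, inhibition c*)
    "b", "c", "b2", "c2", "b3", "c3", "b4", "c4", "b5", "c5",
    # activation / inhibition thresholds (Ki6/c6: REV_n repression of Cry)
    "Kt1", "Kt2", "Kt3", "Kt4", "Kt5",
    "Ki1", "Ki2", "Ki3", "Ki4", "Ki5", "Ki6", "c6",
    # mRNA degradation
    "d_y1", "d_y2", "d_y3", "d_y4", "d_y5",
    # translation
    "k_p1", "k_p2", "k_p3", "k_p4", "k_p5",
    # PER phosphorylation cycle
    "k_ph", "k_dph",
    # PER/CRY complex formation (unphosphorylated, phosphorylated)
    "k_f1", "k_d1", "k_f2", "k_d2",
    # nuclear import/export
    "k_im1", "k_ex1", "k_im2", "k_ex2", "k_im3", "k_im4", "k_im5",
    # CLOCK/BMAL activation cycle
    "k_act", "k_deact",
    # protein degradation
    "d_x1", "d_x2", "d_x3", "d_x4", "d_x5", "d_x6", "d_x7",
    "d_x8", "d_x9", "d_x10", "d_x11", "d_x12", "d_x13", "d_x14",
)

#: Sense–antisense interaction symbols.  ``mu`` scales Per2 transcription
#: (interference strength), ``lam``/``lam0``/``lam1`` are Per2AS synthesis
#: rates, ``K_S``/``K_AS`` are half-inhibition thresholds, ``d_AS`` the
#: Per2AS degradation rate and (``k_assn``, ``k_diss``, ``d_dup``) the duplex
#: association / dissociation / degradation constants.
ANTISENSE_SYMBOLS: tuple[str, ...] = (
    "mu", "lam", "lam0", "lam1", "K_S", "K_AS", "d_AS",
    "k_assn", "k_diss", "d_dup",
)

ALL_SYMBOLS: tuple[str, ...] = CORE_SYMBOLS + ANTISENSE_SYMBOLS


class ParameterSet(Mapping):
    """Immutable named map of model rate constants.

    Parameters
    ----------
    values
        Mapping from symbol to non-negative real value.
    name
        Provenance label (e.g. ``"WT"``, ``"ensemble-member"``).
    """

    __slots__ = ("_values", "name")

    def __init__(self, values: Mapping[str, float], name: str = "custom"):
        clean: dict[str, float] = {}
        for key, raw in values.items():
            val = float(raw)
            if not math.isfinite(val):
                raise ValueError(f"parameter {key!r} is not finite: {raw!r}")
            if val < 0:
                raise ValueError(f"parameter {key!r} must be >= 0, got {val}")
            if key in _STRICTLY_POSITIVE and val == 0:
                raise ValueError(f"parameter {key!r} must be > 0")
            clean[key] = val
        self._values = clean
        self.name = str(name)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key: str) -> float:
        try:
            return self._values[key]
        except KeyError:
            raise KeyError(f"unparameterized symbol: {key!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        return f"ParameterSet({self.name!r}, {len(self)} symbols)"

    def __eq__(self, other) -> bool:
        if isinstance(other, ParameterSet):
            return self._values == other._values
        return NotImplemented

    def __hash__(self):
        return hash(tuple(sorted(self._values.items())))

    # Convenience ----------------------------------------------------------
    def replace(self, name: str | None = None, **changes: float) -> "ParameterSet":
        """Return a new set with ``changes`` applied on top of this one."""
        merged = dict(self._values)
        merged.update(changes)
        return ParameterSet(merged, name=name if name is not None else self.name)

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def fingerprint(self) -> str:
        """Short stable hash of the (symbol, value) pairs, for provenance."""
        import hashlib

        blob = ";".join(f"{k}={v!r}" for k, v in sorted(self._values.items()))
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    def require(self, *symbols: str) -> None:
        """Raise ``KeyError`` naming every missing symbol, if any."""
        missing = [s for s in symbols if s not in self._values]
        if missing:
            raise KeyError(f"unparameterized symbols: {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Plain-text parameter files:  "name = value" lines, '#' comments.
# ---------------------------------------------------------------------------

def load_parameter_file(path, name: str | None = None) -> ParameterSet:
    """Read a ``name = value`` parameter file into a :class:`ParameterSet`."""
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ValueError(f"{path}:{lineno}: expected 'name = value', got {line!r}")
            key, _, rhs = stripped.partition("=")
            key = key.strip()
            try:
                values[key] = float(rhs.strip())
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {rhs.strip()!r}") from err
    return ParameterSet(values, name=name if name is not None else "file")


def write_parameter_file(params: ParameterSet, path) -> None:
    """Write ``params`` as a ``name = value`` file (full float precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# parameter set: {params.name}\n")
        for key in params:
            fh.write(f"{key} = {params[key]!r}\n")


_PAR_LINE = re.compile(r"^\s*par(?:am|ameters?)?\s+(.*)$", re.IGNORECASE)
_ASSIGN = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)\s*=\s*([-+0-9.eE]+)$")


def parse_ode_parameters(path, name: str | None = None) -> ParameterSet:
    """Extract ``par name=value`` declarations from an XPPAUT-style .ode file.

    Comma-separated lists (``par a=12, V1max=1``) are supported; all other
    lines (equations, init, options) are ignored.  A malformed assignment on a
    ``par`` line raises ``ValueError`` with the offending line number.
    """
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].rstrip()
            match = _PAR_LINE.match(body)
            if not match:
                continue
            for chunk in match.group(1).split(","):
                chunk = chunk.strip()
                if not chunk:
                    continue
                assign = _ASSIGN.match(chunk)
                if assign is None:
                    raise ValueError(f"{path}:{lineno}: malformed par assignment {chunk!r}")
                values[assign.group(1)] = float(assign.group(2))
    return ParameterSet(values, name=name if name is not None else "ode-file")


def _data_path(filename: str):
    return resources.files("per2as").joinpath("data", filename)


def wt_parameters() -> ParameterSet:
    """The calibrated wild-type parameter table shipped with the package."""
    with resources.as_file(_data_path("wt.params")) as path:
        params = load_parameter_file(path, name="WT")
    params.require(*ALL_SYMBOLS)
    return params
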