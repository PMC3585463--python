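"""Model parameters, state vector, validation, and config I/O.

The model couples three sub-systems: the beta-cell cycle (three phases
G1 / S / G2M with a glucose-modulated G1->S transition), blood glucose and
insulin concentrations, and a two-compartment insulin storage (releasable
X1 / non-releasable X2) driven by a glucose-dependent provision factor P.

Units follow the published parameter table at face value: time in minutes,
glucose and insulin concentrations in mg/100ml, insulin masses in mg, cell
counts dimensionless.  The blood volume ``bv`` is in ml and enters the
insulin equation as a bare 1/bv factor with no per-100ml conversion; the
parameter values were evidently tuned under that convention and the package
performs no unit algebra.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, NamedTuple

__all__ = [
    "ParameterSet",
    "StateVector",
    "Violation",
    "ConfigError",
    "STATE_FIELDS",
    "DEFAULT_G1_INITIAL",
    "default_parameters",
    "default_initial_state",
    "validate",
    "load_config",
    "save_config",
]

#: Canonical component ordering used everywhere (RHS, Jacobian, CSV columns).
STATE_FIELDS: tuple[str, ...] = ("G1", "S", "G2M", "G", "I", "X1", "X2", "P")

#: Initial number of beta-cells in G1-phase; normalizes the per-cell insulin
#: content p12 = Xbar_max / G1(0).
DEFAULT_G1_INITIAL = 958_000.0

#: Printed (rounded) value of the per-cell insulin amount.
PRINTED_P12 = 1.72e-9


@dataclass(frozen=True)
class ParameterSet:
    """The 19 model constants.

    Attributes
    ----------
    p1, p2, p3 : float
        Cell-cycle transition rates G1->S, S->G2M, G2M->G1 [1/min].
    p4 : float
        Apoptosis rate acting on G1-phase cells [1/min].
    p5 : float
        Linear glucose influence factor on the G1->S transition [100ml/mg].
    p6 : float
        Net glucose production rate (liver minus insulin-independent brain
        uptake) [mg/(100ml min)].
    p7 : float
        Glucose effectiveness at zero insulin [1/min].
    p8 : float
        Insulin sensitivity of target cells [100ml/(mg min)].
    p9 : float
        Insulin secretion rate from the releasable store [1/min].
    p10 : float
        Insulin decay rate in blood [1/min].
    p11 : float
        Relaxation rate of the provision factor toward P_inf [1/min].
    p12 : float
        Insulin amount per beta-cell [mg]; Xmax(t) = p12 * G1(t).
    bv : float
        Blood volume of the organism [ml].
    f : float
        Provision proportionality factor [dimensionless]; must satisfy
        f < p9 for the redistribution factor to stay finite.
    h, P0 : float
        Hill coefficient and Michaelis constant of the provision steady
        state P_inf(G) = G^h / (P0^h + G^h).
    Xbar_max : float
        Maximal amount of insulin per pancreas at the reference cell
        mass G1(0) [mg].
    k, C : float
        Hill coefficient and Michaelis constant of the sigmoid packet
        threshold distribution X*(G) = Xmax G^k / (C^k + G^k).
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float
    p9: float
    p10: float
    p11: float
    p12: float
    bv: float
    f: float
    h: float
    P0: float
    Xbar_max: float
    k: float
    C: float

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given fields overridden."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigError(f"unknown parameter field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class StateVector:
    """The 8 dynamical variables, in the fixed order of ``STATE_FIELDS``.

    G1, S, G2M are cell counts per phase; G and I blood glucose/insulin
    concentrations [mg/100ml]; X1, X2 releasable/non-releasable stored
    insulin [mg]; P the dimensionless provision factor.
    """

    G1: float
    S: float
    G2M: float
    G: float
    I: float
    X1: float
    X2: float
    P: float

    def as_array(self):
        import numpy as np

        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, x) -> "StateVector":
        if len(x) != len(STATE_FIELDS):
            raise ValueError(f"state vector must have {len(STATE_FIELDS)} components")
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, x)})

    def replace(self, **overrides: float) -> "StateVector":
        unknown = set(overrides) - set(STATE_FIELDS)
        if unknown:
            raise ConfigError(f"unknown state field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


class Violation(NamedTuple):
    """A single validation failure: which field, which rule."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration input."""


def default_parameters(printed_p12: bool = False) -> ParameterSet:
    """Published default parameter set.

    p12 is recomputed as ``Xbar_max / G1(0)`` = 1.7223e-9 mg so that the
    storage capacity at the initial cell mass equals ``Xbar_max`` exactly
    (the printed table rounds it to 1.72e-9).  Pass ``printed_p12=True``
    for the verbatim rounded value.
    """
    xbar = 1.65e-3
    p12 = PRINTED_P12 if printed_p12 else xbar / DEFAULT_G1_INITIAL
    return ParameterSet(
        p1=6.0594e-5,
        p2=4.9861e-3,
        p3=8.9444e-4,
        p4=3.3194e-4,
        p5=0.0561,
        p6=0.3,
        p7=0.003,
        p8=360e-3,
        p9=0.622,
        p10=0.3,
        p11=0.0337,
        p12=p12,
        bv=3.33,
        f=0.5,
        h=5.0,
        P0=186.506,
        Xbar_max=xbar,
        k=3.3,
        C=149.78,
    )


def default_initial_state() -> StateVector:
    """Published initial values: post-prandial hyperglycemia (G = 200)."""
    return StateVector(
        G1=DEFAULT_G1_INITIAL,
        S=14_000.0,
        G2M=28_000.0,
        G=200.0,
        I=0.01,
        X1=0.0012,
        X2=0.0005,
        P=0.0,
    )


def validate(params: ParameterSet) -> list[Violation]:
    """Check parameter invariants; return a (possibly empty) violation list.

    Rules:

    * every field strictly positive;
    * ``p4 > p1`` — otherwise the cell-cycle glucose threshold
      Ghat = (p4 - p1)/(p1 p5) is not positive;
    * ``f < p9`` — otherwise the denominator
      f G^h (1 + C^k G^-k) - p9 (P0^h + G^h) of the redistribution factor
      changes sign for large G (asymptotically (f - p9) G^h) and the factor
      blows up at the crossing.
    """
    out: list[Violation] = []
    for fld in dataclasses.fields(params):
        v = getattr(params, fld.name)
        if not (isinstance(v, (int, float)) and math.isfinite(v)):
            out.append(Violation(fld.name, "must be a finite number"))
        elif v <= 0:
            out.append(Violation(fld.name, "must be strictly positive"))
    if params.p4 <= params.p1:
        out.append(Violation("p4", "p4 > p1 required (glucose threshold Ghat <= 0)"))
    if params.f >= params.p9:
        out.append(Violation("f", "f < p9 required (redistribution denominator changes sign)"))
    return out


# ---------------------------------------------------------------------------
# Config I/O.  JSON is canonical; .yaml/.yml read through pyyaml.
# Schema: {"parameters": {...}, "initial_state": {...},
#          "scenario": {"name": str, "duration_min": num, "overrides": {...}}}
# Unknown keys are hard errors: a silently ignored typo in a parameter name is
# the classic simulator-config failure mode.
# ---------------------------------------------------------------------------

_TOP_KEYS = {"parameters", "initial_state", "scenario"}
_SCENARIO_KEYS = {"name", "duration_min", "overrides", "output_dt_min"}


def _check_numeric(mapping: Mapping[str, Any], allowed: set[str], where: str) -> dict[str, float]:
    out = {}
    for key, val in mapping.items():
        if key not in allowed:
            raise ConfigError(f"unknown field '{where}.{key}'")
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise ConfigError(f"non-numeric value for '{where}.{key}': {val!r}")
        out[key] = float(val)
    return out


def load_config(path: str | Path) -> tuple[ParameterSet, StateVector, dict[str, Any]]:
    """Load (parameters, initial state, scenario dict) from JSON or YAML.

    Fields absent from the file keep their defaults.  Unknown field names
    and non-numeric values raise :class:`ConfigError` naming the field path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML config {path}: {exc}") from exc
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse JSON config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping in {path}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s) in {path}: {sorted(unknown)}")

    params = default_parameters()
    pfields = {f.name for f in dataclasses.fields(params)}
    if "parameters" in raw:
        params = params.replace(**_check_numeric(raw["parameters"], pfields, "parameters"))
    init = default_initial_state()
    if "initial_state" in raw:
        init = init.replace(**_check_numeric(raw["initial_state"], set(STATE_FIELDS), "initial_state"))
    scenario: dict[str, Any] = {}
    if "scenario" in raw:
        sc = raw["scenario"]
        unknown = set(sc) - _SCENARIO_KEYS
        if unknown:
            raise ConfigError(f"unknown field(s) in scenario: {sorted(unknown)}")
        scenario = dict(sc)
        if "overrides" in scenario:
            scenario["overrides"] = _check_numeric(scenario["overrides"], pfields, "scenario.overrides")
    return params, init, scenario


def save_config(
    path: str | Path,
    params: ParameterSet,
    init: StateVector | None = None,
    scenario: Mapping[str, Any] | None = None,
) -> None:
    """Write a config JSON; round-trips bit-exactly through ``load_config``."""
    doc: dict[str, Any] = {"parameters": params.as_dict()}
    if init is not None:
        doc["initial_state"] = init.as_dict()
    if scenario:
        doc["scenario"] = dict(scenario)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
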