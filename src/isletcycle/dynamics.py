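"""Right-hand sides of the coupled glucose-insulin-cell-cycle system.

The assembled 8-state autonomous ODE, in the fixed component order
(G1, S, G2M, G, I, X1, X2, P):

    dG1/dt  = 2 p3 G2M - (p1 (1 + p5 G) + p4) G1
    dS/dt   = p1 (1 + p5 G) G1 - p2 S
    dG2M/dt = p2 S - p3 G2M
    dG/dt   = p6 - (p7 + p8 I) G
    dI/dt   = (1/bv) p9 X1 - p10 I
    dX1/dt  =  X1 (xi*(G)/A) dG/dt - p9 X1 + ft_A X2 - ft_B X1 + f A P
    dX2/dt  = -X2 (xi*(G)/B) dG/dt          + ft_B X1 - ft_A X2 + f B P
    dP/dt   = p11 (P_inf(G) - P)

where A, B are the closed-form target-distribution integrals below/above
the current glucose concentration, and ft_A = f_tilde*A, ft_B = f_tilde*B
are the combined redistribution rates (independent of cell mass, so the
system is regular even at G1 = 0).  The factor 2 in dG1/dt accounts for
cell division on the G2M -> G1 transition.  The storage boundary terms
(the dG/dt pieces) move insulin between X1 and X2 as the glucose threshold
sweeps across the packet distribution; they are singular at G = 0, which
motivates the G_MIN guard rail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import STATE_FIELDS, ParameterSet
from .storage import StorageFunctions

__all__ = [
    "G_MIN",
    "AdmissibilityError",
    "rhs_cell_cycle",
    "rhs_blood",
    "rhs_storage",
    "rhs_full",
    "make_rhs",
    "PositivityReport",
    "positivity_condition",
    "POSITIVITY_RANGES",
    "POSITIVITY_SEED",
]

#: Guard rail on blood glucose [mg/100ml]: the storage boundary ratio
#: xi*/A ~ k/G diverges at G = 0, and biologically G stays positive
#: (constant hepatic production p6).  The RHS refuses states at or below it.
G_MIN = 1e-6


class AdmissibilityError(ValueError):
    """State outside the model's admissible domain (G <= G_MIN or non-finite)."""


def rhs_cell_cycle(G1, S, G2M, G, params: ParameterSet):
    """Cell-cycle rates (dG1, dS, dG2M) at fixed glucose concentration G."""
    for name, v in (("G1", G1), ("S", S), ("G2M", G2M), ("G", G)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    trans = params.p1 * (1.0 + params.p5 * G)
    dG1 = 2.0 * params.p3 * G2M - (trans + params.p4) * G1
    dS = trans * G1 - params.p2 * S
    dG2M = params.p2 * S - params.p3 * G2M
    return dG1, dS, dG2M


def rhs_blood(G, I, X1, params: ParameterSet):
    """Blood rates (dG, dI): production minus uptake; secretion minus decay."""
    for name, v in (("G", G), ("I", I), ("X1", X1)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    dG = params.p6 - (params.p7 + params.p8 * I) * G
    dI = params.p9 * X1 / params.bv - params.p10 * I
    return dG, dI


def rhs_storage(G, Gdot, G1, X1, X2, P, params: ParameterSet, sf: StorageFunctions | None = None):
    """Storage rates (dX1, dX2, dP); Gdot must come from :func:`rhs_blood`.

    The redistribution contributions ft_B*X1 - ft_A*X2 appear with opposite
    signs in dX1 and dX2 and never change X1 + X2.  The boundary terms are
    not mutually conservative unless X1/A = X2/B; that is a property of the
    published reduction, taken at face value.
    """
    if G <= G_MIN:
        raise AdmissibilityError(f"G = {G} <= G_MIN = {G_MIN}")
    for name, v in (("G1", G1), ("X1", X1), ("X2", X2), ("P", P)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if sf is None:
        sf = StorageFunctions(params)
    ftA, ftB = sf.f_tilde_times_AB(G)
    hill = sf.hill(G)
    fXm = params.f * sf.Xmax(G1)
    fA = fXm * hill
    fB = fXm - fA
    redist = ftB * X1 - ftA * X2
    dX1 = X1 * sf.boundary_ratio_low(G) * Gdot - params.p9 * X1 - redist + fA * P
    dX2 = -X2 * sf.boundary_ratio_high(G) * Gdot + redist + fB * P
    dP = params.p11 * (sf.P_inf(G) - P)
    return dX1, dX2, dP


def rhs_full(t, state, params: ParameterSet, sf: StorageFunctions | None = None):
    """Assembled 8-component derivative vector (autonomous; t unused).

    ``state`` is an array in ``STATE_FIELDS`` order.  Raises
    :class:`AdmissibilityError` for non-finite input or G <= G_MIN.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (len(STATE_FIELDS),):
        raise ValueError(f"state must have {len(STATE_FIELDS)} components")
    if not np.all(np.isfinite(x)):
        raise AdmissibilityError("non-finite state component")
    G1, S, G2M, G, I, X1, X2, P = x
    dG1, dS, dG2M = rhs_cell_cycle(G1, S, G2M, G, params)
    dG, dI = rhs_blood(G, I, X1, params)
    dX1, dX2, dP = rhs_storage(G, dG, G1, X1, X2, P, params, sf=sf)
    return np.array([dG1, dS, dG2M, dG, dI, dX1, dX2, dP])


def make_rhs(params: ParameterSet):
    """Integrator-facing RHS closure.

    Shares one :class:`StorageFunctions` across calls and converts guard-rail
    violations into NaN rates so an adaptive solver rejects the trial step
    (and ultimately fails loudly) instead of propagating an exception from
    deep inside a stepper.
    """
    sf = StorageFunctions(params)
    nan = np.full(len(STATE_FIELDS), np.nan)

    def rhs(t, x):
        try:
            return rhs_full(t, x, params, sf=sf)
        except (AdmissibilityError, ValueError, FloatingPointError):
            return nan.copy()

    return rhs


# --- Positivity of solutions -------------------------------------------------
#
# The flow stays in the positive orthant iff every component's rate is
# positive on that component's zero face, for all positive values of the
# other components.  The check below samples the faces; the positivity is in
# fact structural (e.g. dX1|_{X1=0} = ft_A X2 + f A P > 0), and the sampled
# minima make that visible per component.

#: Sampling ranges covering all simulated regimes (cells, concentrations,
#: stored masses, provision).  Draws are log-uniform: each range spans
#: several decades.
POSITIVITY_RANGES: dict[str, tuple[float, float]] = {
    "G1": (1.0, 1e9),
    "S": (1.0, 1e9),
    "G2M": (1.0, 1e9),
    "G": (1.0, 600.0),
    "I": (1e-6, 1.0),
    "X1": (1e-9, 1e-2),
    "X2": (1e-9, 1e-2),
    "P": (1e-6, 1.0),
}

#: Default seed for the face sampling (deterministic reports).
POSITIVITY_SEED = 20121119


@dataclass
class PositivityReport:
    """Per-component minimum boundary rate over the sampled faces."""

    min_rates: dict[str, float]
    n_samples: int
    seed: int

    @property
    def passed(self) -> bool:
        return all(v > 0 for v in self.min_rates.values())


def _component_rate(i: int, x: np.ndarray, params: ParameterSet, sf: StorageFunctions) -> float:
    """Rate of component i at the given state, via the sub-model RHS.

    Evaluating only the needed sub-model keeps the G = 0 face well defined:
    dG/dt there is p6 - 0 and involves no storage algebra.
    """
    G1, S, G2M, G, I, X1, X2, P = x
    name = STATE_FIELDS[i]
    if name in ("G1", "S", "G2M"):
        return rhs_cell_cycle(G1, S, G2M, G, params)[i]
    if name in ("G", "I"):
        return rhs_blood(G, I, X1, params)[i - 3]
    Gdot, _ = rhs_blood(G, I, X1, params)
    return rhs_storage(G, Gdot, G1, X1, X2, P, params, sf=sf)[i - 5]


def positivity_condition(
    params: ParameterSet,
    n_samples: int = 10_000,
    seed: int = POSITIVITY_SEED,
) -> PositivityReport:
    """Monte-Carlo check of the boundary positivity condition.

    For each component i, draws ``n_samples`` states with x_i = 0 and the
    other components log-uniform in :data:`POSITIVITY_RANGES`, evaluates the
    i-th rate, and records the minimum.  The report passes iff every
    minimum is strictly positive, which is necessary and sufficient for
    solutions from positive initial data to stay positive.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    sf = StorageFunctions(params)
    lo = np.log([POSITIVITY_RANGES[f][0] for f in STATE_FIELDS])
    hi = np.log([POSITIVITY_RANGES[f][1] for f in STATE_FIELDS])
    mins: dict[str, float] = {}
    for i, name in enumerate(STATE_FIELDS):
        worst = np.inf
        draws = np.exp(rng.uniform(lo, hi, size=(n_samples, len(STATE_FIELDS))))
        draws[:, i] = 0.0
        for x in draws:
            worst = min(worst, _component_rate(i, x, params, sf))
        mins[name] = float(worst)
    return PositivityReport(min_rates=mins, n_samples=n_samples, seed=seed)
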