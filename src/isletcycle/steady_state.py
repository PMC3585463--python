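"""Fixed points of the complete model and their linear stability.

The cell cycle admits exactly two equilibria: the trivial one with no
cells, and a balance point where apoptosis equals the glucose-enhanced
G1->S transition, which pins glucose at the threshold

    Ghat = (p4 - p1) / (p1 p5).

These induce the two fixed points of the full system:

* F1* = (0, 0, 0, p6/p7, 0, 0, 0, P_inf(p6/p7)) — no beta-cells, glucose at
  the insulin-free balance p6/p7;
* F2* — glucose at Ghat, with insulin, stored masses and cell counts
  determined by the remaining balance conditions.  G*, I*, X1*, P* follow
  from the printed closed forms; the cell-cycle components and X2* are
  polished by damped Newton with closed-form seeds (the seeds are already
  a root to machine precision for the default parameters).

Stability is classified from the eigenvalues of a central finite-difference
Jacobian; the matrix is balanced by a diagonal similarity (state scales
span 14 orders of magnitude between cell counts and insulin masses) before
the eigenvalue computation, which leaves the spectrum unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import STATE_FIELDS, ParameterSet, validate
from .storage import StorageFunctions, provision_steady_state, transition_functions
from .dynamics import G_MIN, make_rhs, rhs_full

__all__ = [
    "SteadyStateReport",
    "glucose_threshold",
    "trivial_steady_state",
    "nontrivial_steady_state",
    "jacobian",
    "classify_stability",
    "state_scales",
]


@dataclass
class SteadyStateReport:
    """Fixed-point coordinates plus residual and (optional) spectrum."""

    label: str  # "trivial" | "nontrivial"
    state: np.ndarray  # STATE_FIELDS order
    residual_norm: float  # max_i |rhs_i| / scale_i
    converged: bool
    seed_formulas_used: dict[str, str] = field(default_factory=dict)
    eigenvalues: np.ndarray | None = None
    classification: str | None = None  # "stable" | "unstable" | "marginal"

    def as_dict(self) -> dict:
        out = {
            "label": self.label,
            "state": {f: float(v) for f, v in zip(STATE_FIELDS, self.state)},
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "seed_formulas_used": self.seed_formulas_used,
            "classification": self.classification,
        }
        if self.eigenvalues is not None:
            out["eigenvalues"] = [
                {"re": float(z.real), "im": float(z.imag)} for z in self.eigenvalues
            ]
        return out


def glucose_threshold(params: ParameterSet) -> float:
    """Cell-cycle glucose threshold Ghat = (p4 - p1)/(p1 p5) [mg/100ml].

    Above Ghat beta-cell mass grows (division outpaces apoptosis), below it
    decays.  Requires p4 > p1 for a positive threshold.
    """
    if params.p4 <= params.p1:
        raise ValueError("p4 > p1 required for a positive glucose threshold")
    return (params.p4 - params.p1) / (params.p1 * params.p5)


def state_scales(params: ParameterSet) -> np.ndarray:
    """Representative per-component magnitudes from the closed-form seeds.

    Used for relative residuals, finite-difference steps and Jacobian
    balancing; any positive numbers of the right order work.
    """
    seeds = _closed_form_seeds(params)
    return np.array([max(abs(seeds[f]), 1e-30) for f in STATE_FIELDS])


def _closed_form_seeds(params: ParameterSet) -> dict[str, float]:
    """Printed closed forms for F2* (exact root of the assembled RHS)."""
    p = params
    Gs = glucose_threshold(params)
    Is = (p.p6 - p.p7 * Gs) / (p.p8 * Gs)
    if Is <= 0:
        raise ValueError(
            "nontrivial steady state needs Ghat < p6/p7 (positive insulin demand)"
        )
    X1s = p.bv * p.p10 * Is / p.p9
    Ps = provision_steady_state(Gs, params)
    G1s = p.p9 * X1s / (p.p12 * p.f * Ps)
    Ss = p.p4 * G1s / p.p2
    G2Ms = p.p4 * G1s / p.p3
    # X2 from the dX2 = 0 balance at dG/dt = 0, via the u-identities
    # (u1 = f_tilde*B, u2 = f_tilde*A): u1 X1 - u2 X2 + f B(G1) P = 0.
    u1, u2, u3, u4 = transition_functions(Gs, params)
    sf = StorageFunctions(params)
    X2s = (u1 * X1s + p.f * sf.B(Gs, G1s) * Ps) / u2
    return {"G1": G1s, "S": Ss, "G2M": G2Ms, "G": Gs, "I": Is, "X1": X1s, "X2": X2s, "P": Ps}


def _residual_norm(x: np.ndarray, params: ParameterSet, scales: np.ndarray) -> float:
    r = rhs_full(0.0, x, params)
    return float(np.max(np.abs(r) / scales))


def trivial_steady_state(params: ParameterSet, classify: bool = True) -> SteadyStateReport:
    """F1*: no cells, G = p6/p7, P = P_inf(p6/p7); an exact fixed point."""
    p = params
    Gs = p.p6 / p.p7
    x = np.zeros(len(STATE_FIELDS))
    x[3] = Gs
    x[7] = provision_steady_state(Gs, params)
    scales = state_scales(params)
    res = _residual_norm(x, params, scales)
    rep = SteadyStateReport(
        label="trivial",
        state=x,
        residual_norm=res,
        converged=res < 1e-8,
        seed_formulas_used={"G": "p6/p7", "P": "P_inf(p6/p7)"},
    )
    if classify:
        classify_stability(rep, params)
    return rep


def nontrivial_steady_state(
    params: ParameterSet,
    classify: bool = True,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> SteadyStateReport:
    """F2*: numerical root of the assembled RHS with four components pinned.

    G*, I*, X1*, P* are imposed from the closed forms (each is forced by a
    scalar balance: dG = dI = dP = 0 plus the X1+X2 capacity balance); the
    free components (G1, S, G2M, X2) are solved by damped Newton on the
    residual rows (dS, dG2M, dX1, dX2), seeded with the printed formulas.
    Falls back to long-horizon integration if Newton stalls.
    """
    bad = validate(params)
    if bad:
        raise ValueError(f"invalid parameters: {[str(b) for b in bad]}")
    seeds = _closed_form_seeds(params)
    scales = state_scales(params)
    free = ["G1", "S", "G2M", "X2"]
    free_idx = [STATE_FIELDS.index(f) for f in free]
    res_rows = [STATE_FIELDS.index(f) for f in ("S", "G2M", "X1", "X2")]

    x = np.array([seeds[f] for f in STATE_FIELDS])

    def residual(xf: np.ndarray) -> np.ndarray:
        y = x.copy()
        y[free_idx] = xf
        r = rhs_full(0.0, y, params)
        return r[res_rows] / scales[res_rows]

    xf = x[free_idx].copy()
    fval = residual(xf)
    for _ in range(max_iter):
        if np.max(np.abs(fval)) < tol:
            break
        # finite-difference Jacobian of the 4-dim reduced system
        J = np.empty((4, 4))
        for j in range(4):
            step = 1e-7 * max(abs(xf[j]), scales[free_idx[j]])
            e = np.zeros(4)
            e[j] = step
            J[:, j] = (residual(xf + e) - residual(xf - e)) / (2 * step)
        try:
            dx = np.linalg.solve(J, -fval)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        while lam > 1e-6:
            trial = xf + lam * dx
            if np.all(trial >= 0):
                fnew = residual(trial)
                if np.max(np.abs(fnew)) < np.max(np.abs(fval)):
                    xf, fval = trial, fnew
                    break
            lam /= 2.0
        else:
            break

    x[free_idx] = xf
    res = _residual_norm(x, params, scales)
    if res >= 1e-8:
        x = _integration_fallback(params, x)
        res = _residual_norm(x, params, scales)
    rep = SteadyStateReport(
        label="nontrivial",
        state=x,
        residual_norm=res,
        converged=res < 1e-8,
        seed_formulas_used={
            "G": "(p4-p1)/(p1 p5)",
            "I": "(p6-p7 G*)/(p8 G*)",
            "X1": "bv p10 I*/p9",
            "P": "P_inf(G*)",
            "G1": "p9 X1*/(p12 f P*)",
            "S": "p4 G1*/p2",
            "G2M": "p4 G1*/p3",
            "X2": "(u1 X1* + f B P*)/u2",
        },
    )
    if classify:
        classify_stability(rep, params)
    return rep


def _integration_fallback(params: ParameterSet, x0: np.ndarray) -> np.ndarray:
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        make_rhs(params), (0.0, 1e6), np.maximum(x0, 0.0), method="RK45",
        rtol=1e-10, atol=state_scales(params) * 1e-12,
    )
    return sol.y[:, -1]


def jacobian(
    state: np.ndarray,
    params: ParameterSet,
    eps_rel: float = 1e-6,
    scales: np.ndarray | None = None,
) -> np.ndarray:
    """Central finite-difference Jacobian of the assembled RHS (8x8).

    The step for component j is ``eps_rel * max(|x_j|, scale_j)`` with
    scales defaulting to the closed-form seed magnitudes, so zero components
    (e.g. at F1*) still get a sensible step.
    """
    if not (1e-10 < eps_rel < 1e-2):
        raise ValueError("eps_rel out of the supported range (1e-10, 1e-2)")
    x = np.asarray(state, dtype=float)
    if scales is None:
        scales = state_scales(params)
    n = len(STATE_FIELDS)
    J = np.empty((n, n))
    for j in range(n):
        step = eps_rel * max(abs(x[j]), scales[j])
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        xm[j] = max(xm[j], G_MIN * 2) if j == 3 else max(xm[j], 0.0)
        J[:, j] = (rhs_full(0.0, xp, params) - rhs_full(0.0, xm, params)) / (xp[j] - xm[j])
    if not np.all(np.isfinite(J)):
        bad = np.argwhere(~np.isfinite(J))[0]
        raise FloatingPointError(f"non-finite Jacobian entry at (row, col) = {tuple(bad)}")
    return J


def classify_stability(
    report: SteadyStateReport,
    params: ParameterSet,
    eps_rel: float = 1e-6,
) -> str:
    """Eigenvalue classification at the report's fixed point.

    The Jacobian is balanced as S^-1 J S with S = diag(state scales) — a
    similarity transform, so the spectrum is exact — before eigenvalue
    extraction.  A fixed point is stable iff every real part is below
    -tol, unstable iff any exceeds +tol, marginal otherwise, with
    tol = 1e-12 * spectral radius.
    """
    scales = state_scales(params)
    J = jacobian(report.state, params, eps_rel=eps_rel, scales=scales)
    Jb = J * (scales[None, :] / scales[:, None])
    eig = np.linalg.eigvals(Jb)
    rho = float(np.max(np.abs(eig)))
    tol = 1e-12 * rho
    re = eig.real
    if np.all(re < -tol):
        label = "stable"
    elif np.any(re > tol):
        label = "unstable"
    else:
        label = "marginal"
    report.eigenvalues = eig
    report.classification = label
    return label
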