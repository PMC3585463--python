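"""Algebra of the insulin-storage model (packet-distribution closed forms).

Stored insulin is pictured as packets, each with a glucose release
threshold theta.  The storage relaxes toward a target density

    xi*(theta, t) = Xmax(t) * k C^k theta^(k-1) / (C^k + theta^k)^2,

the derivative of the sigmoid dose-response X*(G, t) = Xmax(t) G^k/(C^k+G^k),
with the capacity Xmax(t) = p12 * G1(t) scaling linearly in beta-cell mass.
Packets below the current glucose concentration are releasable (X1), those
above are not (X2).  All integrals of xi* are available in closed form, so
every function here is algebraic; this module carries no state.

The redistribution factor f_tilde couples the two compartments so that the
capacity bound X1 + X2 <= Xmax holds in steady state.  Its denominator
D(G) = f G^h (1 + C^k G^-k) - p9 (P0^h + G^h) is strictly negative for all
G > 0 whenever f < p9 (asymptotically (f - p9) G^h), which validation
enforces; the numerator is negative too, so f_tilde > 0.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "provision_steady_state",
    "xmax",
    "target_cumulative",
    "target_density",
    "compartment_integrals",
    "redistribution_factor",
    "transition_functions",
    "denominator",
    "StorageFunctions",
]


def _require_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def _require_pos(name: str, value) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ValueError(f"{name} must be strictly positive")


def _powneg(theta, expo: float):
    """theta**expo for expo possibly non-integer, defined as 0 at theta=0.

    Valid because every exponent used here is positive (k > 1 implies
    k - 1 > 0); avoids 0**real NaN edge cases with array input.
    """
    arr = np.asarray(theta, dtype=float)
    scalar = arr.ndim == 0
    t = np.atleast_1d(arr)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = np.exp(expo * np.log(t[pos]))
    return float(out[0]) if scalar else out


def provision_steady_state(G, params: ParameterSet):
    """Hill-type provision steady state P_inf(G) = G^h / (P0^h + G^h) in [0, 1)."""
    _require_nonneg("G", G)
    Gh = _powneg(G, params.h)
    return Gh / (params.P0**params.h + Gh)


def xmax(G1, params: ParameterSet):
    """Storage capacity Xmax = p12 * G1 [mg] for the current G1-phase cell mass."""
    _require_nonneg("G1", G1)
    return params.p12 * np.asarray(G1, dtype=float) * 1.0


def target_cumulative(G, G1, params: ParameterSet):
    """Target insulin mass stored below threshold G: Xmax(G1) G^k/(C^k + G^k)."""
    _require_nonneg("G", G)
    _require_nonneg("G1", G1)
    Gk = _powneg(G, params.k)
    return xmax(G1, params) * Gk / (params.C**params.k + Gk)


def target_density(theta, G1, params: ParameterSet):
    """Target packet density xi*(theta) = Xmax k C^k theta^(k-1)/(C^k+theta^k)^2."""
    _require_nonneg("theta", theta)
    _require_nonneg("G1", G1)
    Ck = params.C**params.k
    tk = _powneg(theta, params.k)
    tkm1 = _powneg(theta, params.k - 1.0)
    return xmax(G1, params) * params.k * Ck * tkm1 / (Ck + tk) ** 2


def compartment_integrals(G, G1, params: ParameterSet):
    """Closed-form split of the target distribution at threshold G.

    Returns ``(A, B)`` with ``A = int_0^G xi* dtheta = Xmax G^k/(C^k+G^k)``
    and ``B = int_G^inf xi* dtheta = Xmax C^k/(C^k+G^k)``; the identity
    ``A + B = Xmax`` is exact.
    """
    _require_nonneg("G", G)
    _require_nonneg("G1", G1)
    Ck = params.C**params.k
    Gk = _powneg(G, params.k)
    Xm = xmax(G1, params)
    return Xm * Gk / (Ck + Gk), Xm * Ck / (Ck + Gk)


def denominator(G, params: ParameterSet):
    """Shared denominator D(G) = f G^h (1 + C^k G^-k) - p9 (P0^h + G^h).

    Strictly negative for all G > 0 when f < p9.
    """
    _require_pos("G", G)
    p = params
    Gh = _powneg(G, p.h)
    Ck = p.C**p.k
    Gmk = _powneg(G, -p.k)
    return p.f * Gh * (1.0 + Ck * Gmk) - p.p9 * (p.P0**p.h + Gh)


def redistribution_factor(G, G1, params: ParameterSet):
    """Glucose-dependent redistribution rate f_tilde(G, G1) > 0.

        f_tilde = -p9 f C^k G^(h-k) / [ Xmax(G1) * D(G) ]

    with Xmax(G1) = p12 G1 standing for the printed Xbar_max G1/G1(0)
    (identical under the p12 = Xbar_max/G1(0) normalization).  Scales as
    1/G1; finite for all G > 0 when f < p9.
    """
    _require_pos("G", G)
    _require_pos("G1", G1)
    p = params
    den = xmax(G1, params) * denominator(G, params)
    if np.any(np.abs(np.asarray(den)) < 1e-300):
        raise ZeroDivisionError("redistribution denominator at machine scale; need f < p9")
    num = -p.p9 * p.f * p.C**p.k * _powneg(G, p.h - p.k)
    return num / den


def transition_functions(G, params: ParameterSet):
    """Closed-form transition functions ``(u1, u2, u3, u4)`` of glucose.

    u1 = f_tilde*B and u2 = f_tilde*A (both independent of G1 because
    f_tilde ~ 1/Xmax); u3 and u4 carry the 1/G1(0) normalization through
    p12, so that u3*G1 = f*A(G, G1) and u4*G1 = f*B(G, G1).
    """
    _require_pos("G", G)
    p = params
    Ck = p.C**p.k
    D = denominator(G, params)
    Gk = _powneg(G, p.k)
    shared = -p.p9 * p.f * _powneg(G, p.h - p.k) / (D * (Ck + Gk))
    u1 = shared * Ck * Ck
    u2 = shared * Gk * Ck
    u3 = p.f * p.p12 * Gk / (Ck + Gk)
    u4 = p.f * p.p12 * Ck / (Ck + Gk)
    return u1, u2, u3, u4


class StorageFunctions:
    """Pure-function bundle over a fixed :class:`ParameterSet`.

    Precomputes the constant powers (C^k, P0^h) once; used by the RHS hot
    path.  ``boundary_ratio_low``/``boundary_ratio_high`` are the Xmax-free
    ratios xi*(G)/A(G) = k C^k / (G (C^k + G^k)) and
    xi*(G)/B(G) = k G^(k-1) / (C^k + G^k) appearing in the moving-threshold
    boundary terms of the storage ODEs.
    """

    def __init__(self, params: ParameterSet):
        self.params = params
        self._Ck = params.C**params.k
        self._P0h = params.P0**params.h

    # scalar fast paths (no input validation; the RHS guards admissibility)
    def P_inf(self, G: float) -> float:
        Gh = G**self.params.h
        return Gh / (self._P0h + Gh)

    def Xmax(self, G1: float) -> float:
        return self.params.p12 * G1

    def hill(self, G: float) -> float:
        """G^k / (C^k + G^k)."""
        Gk = G**self.params.k
        return Gk / (self._Ck + Gk)

    def A(self, G: float, G1: float) -> float:
        return self.Xmax(G1) * self.hill(G)

    def B(self, G: float, G1: float) -> float:
        return self.Xmax(G1) * (1.0 - self.hill(G))

    def xi_star(self, theta: float, G1: float) -> float:
        p = self.params
        tk = theta**p.k
        return self.Xmax(G1) * p.k * self._Ck * theta ** (p.k - 1.0) / (self._Ck + tk) ** 2

    def X_star(self, G: float, G1: float) -> float:
        return self.A(G, G1)

    def boundary_ratio_low(self, G: float) -> float:
        Gk = G**self.params.k
        return self.params.k * self._Ck / (G * (self._Ck + Gk))

    def boundary_ratio_high(self, G: float) -> float:
        Gk = G**self.params.k
        return self.params.k * G ** (self.params.k - 1.0) / (self._Ck + Gk)

    def f_tilde(self, G: float, G1: float) -> float:
        return redistribution_factor(G, G1, self.params)

    def f_tilde_times_AB(self, G: float) -> tuple[float, float]:
        """(f_tilde*A, f_tilde*B) = (u2, u1): G1-independent, regular at G1=0."""
        p = self.params
        Gh = G**p.h
        Gk = G**p.k
        D = p.f * Gh * (1.0 + self._Ck / Gk) - p.p9 * (self._P0h + Gh)
        shared = -p.p9 * p.f * Gh / Gk / (D * (self._Ck + Gk))
        return shared * Gk * self._Ck, shared * self._Ck * self._Ck

    def u(self, G: float) -> tuple[float, float, float, float]:
        return transition_functions(G, self.params)
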