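"""Algebra of the local-translation circuit.

Right-hand side of the delayed system

    dx/dt = f_x(y(t - tau_e)) + k_rz * z(t - tau_r) - (k_rx + k_dx) * x
    dy/dt = f_a(x(t - tau_a)) * (y0 - y) - f_b(x(t - tau_b)) * y
    dz/dt = k_rx * x - (k_rz + k_dz) * z

with generalized Hill control functions

    f_d(u) = k_d0 + k_d * (u/K_d)^h_d / (1 + (u/K_d)^h_d),   d in {x, a, b}.

Activation (f_a) and suppression (f_b) of translation are driven by the
lagged receptor pool; synthesis/incorporation (f_x) is driven by the
lagged active-FMRP pool.  Delays drop out at equilibrium, so fixed points
of the delayed system coincide with those of the reduced ODE and can be
found from a scalar residual in x alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .parameters import ModelParameters, ParameterDomainError

__all__ = [
    "State",
    "Equilibrium",
    "hill_rate",
    "model_rhs",
    "equilibrium_residual",
    "find_equilibria",
]


class State(NamedTuple):
    """One point of the phase space (all concentrations, nonnegative)."""

    x: float  # active membrane receptors
    y: float  # active FMRP
    z: float  # receptors in the recycling endosome


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the circuit with its residual under substitution."""

    state: State
    residual: float
    stability_hint: str | None = None  # from the zero-delay Jacobian


def hill_rate(u, k0: float, k: float, K: float, h: float):
    """Generalized Hill rate ``k0 + k (u/K)^h / (1 + (u/K)^h)``.

    Monotone nondecreasing in ``u`` and bounded in ``[k0, k0 + k]``.
    Accepts scalar or array ``u``.
    """
    if K <= 0:
        raise ParameterDomainError(f"half-saturation K must be > 0, got {K}")
    if h < 1:
        raise ParameterDomainError(f"Hill coefficient h must be >= 1, got {h}")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ParameterDomainError("Hill argument u must be >= 0")
    # (u/K)^h overflows to inf for extreme u; the saturated limit is k0 + k
    with np.errstate(over="ignore", invalid="ignore"):
        r = (u / K) ** h
        out = k0 + k * r / (1.0 + r)
    out = np.where(np.isfinite(r), out, k0 + k)
    return out if out.ndim else float(out)


def _f_x(u, p: ModelParameters):
    return hill_rate(u, p.k_x0, p.k_x, p.K_x, p.h_x)


def _f_a(u, p: ModelParameters):
    return hill_rate(u, p.k_a0, p.k_a, p.K_a, p.h_a)


def _f_b(u, p: ModelParameters):
    return hill_rate(u, p.k_b0, p.k_b, p.K_b, p.h_b)


def model_rhs(
    now: State,
    x_lag_a: float,
    x_lag_b: float,
    y_lag_e: float,
    z_lag_r: float,
    p: ModelParameters,
) -> tuple[float, float, float]:
    """Time-derivatives (dx/dt, dy/dt, dz/dt) given current state and lags."""
    x, y, z = now
    if min(x, y, z, x_lag_a, x_lag_b, y_lag_e, z_lag_r) < 0:
        raise ParameterDomainError("state and lagged values must be >= 0")
    dx = _f_x(y_lag_e, p) + p.k_rz * z_lag_r - (p.k_rx + p.k_dx) * x
    dy = _f_a(x_lag_a, p) * (p.y0 - y) - _f_b(x_lag_b, p) * y
    dz = p.k_rx * x - (p.k_rz + p.k_dz) * z
    return float(dx), float(dy), float(dz)


def _equilibrium_yz(x, p: ModelParameters):
    """y* and z* implied by a candidate x* (derivatives of y, z set to zero)."""
    fa = _f_a(x, p)
    fb = _f_b(x, p)
    denom = fa + fb
    y = np.where(denom > 0, fa * p.y0 / np.where(denom > 0, denom, 1.0), 0.0)
    z = p.k_rx * x / (p.k_rz + p.k_dz) if (p.k_rz + p.k_dz) > 0 else np.zeros_like(x)
    return y, z


def equilibrium_residual(x, p: ModelParameters):
    """Scalar residual g(x*) whose roots are the equilibria of the circuit.

    Substituting y*(x*) and z*(x*) into the x-equation gives
    ``g(x) = f_x(y*(x)) + k_rz z*(x) - (k_rx + k_dx) x``.
    """
    x = np.asarray(x, dtype=float)
    y, z = _equilibrium_yz(x, p)
    g = _f_x(y, p) + p.k_rz * z - (p.k_rx + p.k_dx) * x
    return g if g.ndim else float(g)


def _stability_hint(eq: State, p: ModelParameters) -> str:
    """Classify the zero-delay Jacobian at a fixed point (a hint only:
    delays can destabilise points that are stable without them)."""
    x, y, z = eq
    h = 1e-7

    def rhs(v):
        return np.array(model_rhs(State(*v), v[0], v[0], v[1], v[2], p))

    v0 = np.array([x, y, z], dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        vp = v0.copy()
        vp[j] += h
        vm = v0.copy()
        vm[j] = max(vm[j] - h, 0.0)
        J[:, j] = (rhs(vp) - rhs(vm)) / (vp[j] - vm[j])
    re = np.linalg.eigvals(J).real
    return "stable(no-delay)" if np.all(re < 0) else "unstable(no-delay)"


def find_equilibria(
    p: ModelParameters,
    x_max: float = 50.0,
    grid_n: int = 4096,
    tol: float = 1e-12,
    with_stability: bool = True,
) -> list[Equilibrium]:
    """Locate all fixed points by a sign scan of the scalar residual.

    Scans ``g(x)`` on a uniform grid over [0, x_max] and refines every
    sign change by Brent's method.  When both constitutive rates k_a0 and
    k_x0 vanish the origin is a forced root and is always included.
    """
    if x_max <= 0:
        raise ParameterDomainError(f"x_max must be > 0, got {x_max}")
    if grid_n < 2:
        raise ParameterDomainError(f"grid_n must be >= 2, got {grid_n}")
    xs = np.linspace(0.0, x_max, grid_n)
    g = equilibrium_residual(xs, p)
    roots: list[float] = []
    if p.k_a0 == 0.0 and p.k_x0 == 0.0:
        roots.append(0.0)
    for i in range(grid_n - 1):
        a, b = g[i], g[i + 1]
        if a == 0.0 and xs[i] not in roots:
            roots.append(xs[i])
        elif a * b < 0:
            r = brentq(lambda u: equilibrium_residual(u, p), xs[i], xs[i + 1],
                       xtol=tol, rtol=1e-15)
            if not any(abs(r - q) < 1e-9 * max(1.0, x_max) for q in roots):
                roots.append(r)
    if g[-1] == 0.0 and not any(abs(x_max - q) < 1e-12 for q in roots):
        roots.append(x_max)

    out: list[Equilibrium] = []
    for r in sorted(roots):
        y, z = _equilibrium_yz(np.float64(r), p)
        st = State(float(r), float(y), float(z))
        res = float(np.max(np.abs(model_rhs(st, st.x, st.x, st.y, st.z, p))))
        hint = _stability_hint(st, p) if with_stability else None
        out.append(Equilibrium(state=st, residual=res, stability_hint=hint))
    return out
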