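"""Cargo mechanics: linkage force law, force balance, thermal density.

The cargo hangs from every engaged motor through an elastic tether that
is slack below its rest length ``l0`` and Hookean beyond it.  Because
the cargo relaxes much faster than the motor kinetics, its position is
pinned (up to thermal fluctuations) at the equilibrium ``x_eq`` where
the tether forces balance the constant load.  The total tether force is
piecewise linear and monotone in the cargo position, so the balance is
solved exactly by scanning the breakpoints ``a_k +- l0`` — no iterative
root finder is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import ModelParameters
from .state_space import AbsoluteConfiguration

_PLATEAU_TOL = 1e-12


class MechanicsError(ValueError):
    pass


def linkage_force(l: float, p: ModelParameters) -> float:
    """Tether force as a function of its (signed) extension, nN.

    Odd, continuous, monotone non-decreasing: zero in the slack region
    |l| < l0, Hookean with stiffness k_el beyond.
    """
    if l >= p.l0:
        return p.k_el * (l - p.l0)
    if l <= -p.l0:
        return p.k_el * (l + p.l0)
    return 0.0


def motor_load(a_k: float, x: float, p: ModelParameters) -> float:
    """Force the cargo exerts on a motor at position a_k, cargo at x.

    Positive when it opposes the motor's motion (motor ahead of the
    cargo), negative when it assists (motor behind).
    """
    return linkage_force(a_k - x, p)


@dataclass(frozen=True)
class EquilibriumSolution:
    x_eq: float                       # cargo equilibrium position, nm
    motor_loads: dict[int, float]     # site index -> load per motor, nN
    flat_interval: bool               # balance held on an interval


def _net_force(x: float, positions, counts, p: ModelParameters) -> float:
    """Net forward force on the cargo at position x (tethers minus load)."""
    return sum(
        z * linkage_force(a - x, p) for a, z in zip(positions, counts)
    ) - p.F_load


def cargo_equilibrium(Z: AbsoluteConfiguration, p: ModelParameters) -> EquilibriumSolution:
    """Exact cargo force balance for a non-empty configuration.

    The net force is piecewise linear and non-increasing in x; its zero
    set is a point or (only when the required tether force is exactly
    zero) an interval, in which case the midpoint is returned with
    ``flat_interval`` set.
    """
    if Z.is_empty:
        raise MechanicsError("cargo equilibrium undefined for the lost-cargo state")
    positions = Z.positions(p)
    counts = Z.counts
    total = Z.motor_count

    breaks = sorted({a + s * p.l0 for a in positions for s in (-1.0, 1.0)})
    g = [_net_force(b, positions, counts, p) for b in breaks]

    roots: list[float] = []
    # left outer piece: all tethers taut forward, slope -k_el*total
    if g[0] <= 0.0:
        slope = -p.k_el * total
        roots.append(breaks[0] - g[0] / slope)
    for i in range(len(breaks) - 1):
        gu, gv = g[i], g[i + 1]
        u, v = breaks[i], breaks[i + 1]
        if u == v:
            continue
        if gu >= 0.0 >= gv:
            if abs(gu - gv) <= _PLATEAU_TOL * max(1.0, abs(gu)):
                if abs(gu) <= _PLATEAU_TOL:
                    roots.extend((u, v))
                continue
            roots.append(u + gu * (v - u) / (gu - gv))
    # right outer piece: all tethers taut backward
    if g[-1] >= 0.0:
        slope = -p.k_el * total
        roots.append(breaks[-1] - g[-1] / slope)

    if not roots:
        raise MechanicsError("force balance has no solution (internal error)")
    x_lo, x_hi = min(roots), max(roots)
    flat = (x_hi - x_lo) > 1e-9
    x_eq = 0.5 * (x_lo + x_hi)
    loads = {k: motor_load(a, x_eq, p) for k, a in zip(Z.sites, positions)}
    return EquilibriumSolution(x_eq=x_eq, motor_loads=loads, flat_interval=flat)


def displacement(Z2: AbsoluteConfiguration, Z: AbsoluteConfiguration,
                 p: ModelParameters) -> float:
    """Shift of the cargo equilibrium across a transition Z -> Z2, nm.

    Transitions into or out of the lost-cargo state contribute zero
    displacement (the run terminates through the absorbing state).
    """
    if Z2.is_empty or Z.is_empty:
        return 0.0
    return cargo_equilibrium(Z2, p).x_eq - cargo_equilibrium(Z, p).x_eq


def truncation_mass() -> float:
    """Probability mass of a standard normal within +-3 sigma."""
    return math.erf(3.0 / math.sqrt(2.0))


def thermal_density(x: float, p: ModelParameters) -> float:
    """Truncated-Gaussian density of the cargo offset from x_eq, 1/nm.

    Gaussian with std sigma_th, truncated to [-3 sigma, 3 sigma] and
    renormalized over that interval; zero outside.
    """
    s = p.sigma_th
    if not s > 0:
        raise MechanicsError("thermal_density requires sigma_th > 0")
    if abs(x) > 3.0 * s:
        return 0.0
    norm = s * math.sqrt(2.0 * math.pi) * truncation_mass()
    return math.exp(-0.5 * (x / s) ** 2) / norm
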