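"""Single-motor kinetics and the configuration-level transition map.

Stepping follows Michaelis-Menten ATP kinetics with a load-dependent
binding efficiency (quadratic decay up to the stall force) and a
load-sensitive backward hydrolysis rate.  Detachment below stall is
tied to stepping through the measured processivity; above stall it is
the constant ramp-off rate ``P_back``.  With thermal cargo noise, each
rate is averaged over the truncated-Gaussian cargo position.

From these single-motor rates the module enumerates every elementary
transition of an absolute configuration (step, detach, attach) and
projects them onto relative-configuration transition rates and mean
cargo displacements.  Translation invariance of the rates makes the
projection representative-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import ModelParameters, thermal_energy
from .state_space import (
    AbsoluteConfiguration,
    RelativeConfiguration,
    StateSpace,
    canonical_representative,
    project,
)
from .mechanics import (
    EquilibriumSolution,
    cargo_equilibrium,
    motor_load,
    thermal_density,
)


def _k_off(F: float, p: ModelParameters) -> float:
    return p.k0_off * math.exp(F * p.d_l / thermal_energy(p))


def binding_efficiency(F: float, p: ModelParameters) -> float:
    """Probability that the free head rebinds under load F (1 below 0,
    quadratic decay to 0 at the stall force)."""
    if F <= 0.0:
        return 1.0
    if F >= p.F_s:
        return 0.0
    return (1.0 - F / p.F_s) ** 2


def step_rate_at_force(F: float, p: ModelParameters) -> float:
    """Forward stepping rate of one motor under constant load F, 1/s."""
    eps = binding_efficiency(F, p)
    if eps == 0.0:
        return 0.0
    km = (p.k_cat + _k_off(F, p)) / p.k_on
    return p.k_cat * p.atp / (p.atp + km) * eps


def processivity(F: float, p: ModelParameters) -> float:
    """Mean single-motor travel before detachment under load F, nm."""
    e = math.exp(-F * p.delta_l / thermal_energy(p))
    return p.d_s * p.atp * p.proc_A * e / (p.atp + p.proc_B * (1.0 + p.proc_A) * e)


def detach_rate_at_force(F: float, p: ModelParameters) -> float:
    """Detachment rate of one motor under constant load F, 1/s.

    Below stall, detachment and stepping are locked together by the
    processivity: P_step/P_detach = L(F)/d_s.  At and above stall the
    rate is the constant P_back.
    """
    if F >= p.F_s:
        return p.P_back
    return step_rate_at_force(F, p) * p.d_s / processivity(F, p)


def _gauss_legendre(order: int):
    return np.polynomial.legendre.leggauss(order)


def _thermal_average(rate_fn, a_k: float, x_eq: float, p: ModelParameters) -> float:
    """Average rate_fn(motor_load(a_k, x)) over the truncated-Gaussian
    cargo position centred at x_eq.

    The integrand has kinks where the tether goes slack/taut and a
    discontinuity where the local load crosses the stall force, so the
    interval is split at those breakpoints and a fixed-order
    Gauss-Legendre rule is applied per smooth piece (deterministic).
    """
    s = p.sigma_th
    if s == 0.0:
        return rate_fn(motor_load(a_k, x_eq, p), p)
    lo, hi = x_eq - 3.0 * s, x_eq + 3.0 * s
    cuts = {lo, hi}
    for b in (
        a_k - p.l0 - p.F_s / p.k_el,  # stall boundary (motor ahead)
        a_k - p.l0,                   # taut/slack (motor ahead)
        a_k + p.l0,                   # slack/taut (motor behind)
    ):
        if lo < b < hi:
            cuts.add(b)
    edges = sorted(cuts)
    nodes, weights = _gauss_legendre(p.quad_order)
    total = 0.0
    for u, v in zip(edges, edges[1:]):
        half = 0.5 * (v - u)
        mid = 0.5 * (u + v)
        xs = mid + half * nodes
        total += half * sum(
            w * rate_fn(motor_load(a_k, x, p), p) * thermal_density(x - x_eq, p)
            for x, w in zip(xs, weights)
        )
    return total


def site_step_rate(Z: AbsoluteConfiguration, k: int, p: ModelParameters,
                   eq: EquilibriumSolution | None = None) -> float:
    """Total stepping rate out of site k (z_k motors, thermally averaged)."""
    z_k = Z.occupancy[k]
    if eq is None:
        eq = cargo_equilibrium(Z, p)
    return z_k * _thermal_average(step_rate_at_force, k * p.d_s, eq.x_eq, p)


def site_detach_rate(Z: AbsoluteConfiguration, k: int, p: ModelParameters,
                     eq: EquilibriumSolution | None = None) -> float:
    """Total detachment rate out of site k (thermally averaged; switches
    to P_back wherever the local load exceeds the stall force)."""
    z_k = Z.occupancy[k]
    if eq is None:
        eq = cargo_equilibrium(Z, p)
    return z_k * _thermal_average(detach_rate_at_force, k * p.d_s, eq.x_eq, p)


@dataclass(frozen=True)
class TransitionEvent:
    """One elementary event of the absolute-configuration chain."""

    kind: str                       # "step" | "detach" | "attach"
    site: int                       # lattice site the event acts on
    rate: float                     # 1/s
    source: AbsoluteConfiguration
    target: AbsoluteConfiguration
    displacement: float             # cargo equilibrium shift, nm
    rearguard: bool = False         # detachment of (one of) the rearguard motor(s)


def _with_delta(Z: AbsoluteConfiguration, k: int, dz: int) -> AbsoluteConfiguration:
    occ = Z.occupancy
    occ[k] = occ.get(k, 0) + dz
    return AbsoluteConfiguration.from_occupancy(occ)


def attachment_events(Z: AbsoluteConfiguration, p: ModelParameters,
                      eq: EquilibriumSolution | None = None) -> list[TransitionEvent]:
    """Attachment of one unattached motor at a slack-reachable site.

    Admissible sites lie within l0 of the cargo equilibrium (the motor
    binds without stretching its tether), all equally likely; the total
    attachment rate is (m_bar - engaged) * P_att.  Attachment does not
    move x_eq (the new tether is slack), so the displacement is 0.
    """
    free = p.m_bar - Z.motor_count
    if free <= 0:
        return []
    if eq is None:
        eq = cargo_equilibrium(Z, p)
    x = eq.x_eq
    k_lo = math.ceil((x - p.l0) / p.d_s - 1e-12)
    k_hi = math.floor((x + p.l0) / p.d_s + 1e-12)
    sites = list(range(k_lo, k_hi + 1))
    if not sites:
        return []
    rate = free * p.P_att if p.att_per_site else free * p.P_att / len(sites)
    return [
        TransitionEvent(
            kind="attach", site=k, rate=rate, source=Z,
            target=_with_delta(Z, k, +1), displacement=0.0,
        )
        for k in sites
    ]


def absolute_transitions(Z: AbsoluteConfiguration, p: ModelParameters,
                         eq: EquilibriumSolution | None = None) -> list[TransitionEvent]:
    """Every elementary transition out of a non-empty configuration.

    One step event per occupied site (omitted when stalled, i.e. zero
    rate), one detach event per occupied site, and the attachment
    events.  When ``n_cap`` is set, events whose target would exceed
    the capped extent are suppressed (approximation mode), identically
    in the exact solver and the stochastic oracle.
    """
    if Z.is_empty:
        raise ValueError("no transitions out of the lost-cargo state")
    if eq is None:
        eq = cargo_equilibrium(Z, p)
    events: list[TransitionEvent] = []
    for k in Z.sites:
        r_step = site_step_rate(Z, k, p, eq)
        if r_step > 0.0:
            target = _with_delta(_with_delta(Z, k, -1), k + 1, +1)
            d = cargo_equilibrium(target, p).x_eq - eq.x_eq
            if abs(d) < 1e-9:
                d = 0.0  # slack-motor step: equilibrium provably unmoved
            events.append(TransitionEvent("step", k, r_step, Z, target, d))
        r_det = site_detach_rate(Z, k, p, eq)
        target = _with_delta(Z, k, -1)
        if target.is_empty:
            d = 0.0
        else:
            d = cargo_equilibrium(target, p).x_eq - eq.x_eq
            if abs(d) < 1e-9:
                d = 0.0
        events.append(
            TransitionEvent("detach", k, r_det, Z, target, d,
                            rearguard=(k == Z.rearguard))
        )
    events.extend(attachment_events(Z, p, eq))
    if p.n_cap is not None:
        events = [e for e in events if e.target.span <= p.n_cap]
    return events


@dataclass(frozen=True)
class TransitionGroup:
    """All elementary events carrying sigma into one target class."""

    source: RelativeConfiguration
    target: RelativeConfiguration
    rate: float                 # lambda_rel, 1/s
    mean_displacement: float    # d_av, rate-weighted, nm
    events: tuple[TransitionEvent, ...]


def relative_rates(sigma: RelativeConfiguration, p: ModelParameters
                   ) -> list[TransitionGroup]:
    """Project the transitions of sigma's canonical representative onto
    relative-configuration classes (rates summed, displacements
    rate-averaged).  Self-transition classes (e.g. the lone motor
    stepping) are retained: they carry displacement but cancel in the
    generator diagonal."""
    Z = canonical_representative(sigma)
    groups: dict[RelativeConfiguration, list[TransitionEvent]] = {}
    for ev in absolute_transitions(Z, p):
        groups.setdefault(project(ev.target), []).append(ev)
    out = []
    for target, evs in groups.items():
        rate = sum(e.rate for e in evs)
        d_av = sum(e.rate * e.displacement for e in evs) / rate if rate > 0 else 0.0
        out.append(TransitionGroup(sigma, target, rate, d_av, tuple(evs)))
    return out


@dataclass(frozen=True)
class RelativeTransitionTable:
    """lambda_rel / d_av for every ordered pair with positive rate."""

    rows: dict[RelativeConfiguration, tuple[TransitionGroup, ...]]

    def groups(self, sigma: RelativeConfiguration) -> tuple[TransitionGroup, ...]:
        return self.rows.get(sigma, ())

    def total_outflow(self, sigma: RelativeConfiguration) -> float:
        return sum(g.rate for g in self.groups(sigma))

    def all_groups(self):
        for groups in self.rows.values():
            yield from groups


def build_table(space: StateSpace, p: ModelParameters) -> RelativeTransitionTable:
    """Transition table over every non-empty state of the space.

    Raises if any transition leaves the space (the model builder is
    responsible for supplying a closed extent, unless n_cap truncates).
    """
    rows = {}
    for sigma in space.nonempty():
        groups = relative_rates(sigma, p)
        for g in groups:
            if not g.target.is_empty and g.target not in space:
                raise ValueError(
                    f"transition {sigma} -> {g.target} leaves the state space "
                    f"(n={space.n}); extent bound not closed"
                )
        rows[sigma] = tuple(groups)
    return RelativeTransitionTable(rows)


def table_to_records(table: RelativeTransitionTable) -> list[dict]:
    """Flat export of the table (one row per ordered state pair)."""
    records = []
    for g in table.all_groups():
        kinds = {}
        for e in g.events:
            kinds[e.kind] = kinds.get(e.kind, 0.0) + e.rate
        records.append(
            {
                "source": str(g.source),
                "target": str(g.target),
                "rate_per_s": g.rate,
                "mean_displacement_nm": g.mean_displacement,
                **{f"rate_{k}_per_s": v for k, v in sorted(kinds.items())},
            }
        )
    return records
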