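"""Stochastic simulation of the absolute-configuration chain.

An event-driven (Gillespie) sampler over exactly the same elementary
rates as the exact solver: it reuses the mechanics and kinetics modules
verbatim, so any disagreement with the master-equation solution
isolates a projection or solver defect.  Translation invariance lets
the simulator memoize the event table per *relative* configuration and
replay it at any absolute position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ModelParameters
from .state_space import (
    AbsoluteConfiguration,
    RelativeConfiguration,
    StateSpace,
    canonical_representative,
    project,
)
from .kinetics import absolute_transitions


@dataclass(frozen=True)
class _CachedEvent:
    kind: str
    site_offset: int          # event site relative to the rearguard
    target: RelativeConfiguration
    rear_shift: int | None    # target rearguard site in canonical frame
    displacement: float
    rearguard: bool


class _EventCache:
    """Per-relative-configuration transition tables (rates memoized)."""

    def __init__(self, p: ModelParameters):
        self.p = p
        self._cache: dict[RelativeConfiguration, tuple] = {}

    def get(self, sigma: RelativeConfiguration):
        hit = self._cache.get(sigma)
        if hit is not None:
            return hit
        Z = canonical_representative(sigma)
        events = absolute_transitions(Z, self.p)
        cached = []
        rates = []
        for ev in events:
            tgt = project(ev.target)
            shift = None if ev.target.is_empty else ev.target.rearguard
            cached.append(
                _CachedEvent(ev.kind, ev.site, tgt, shift, ev.displacement,
                             ev.rearguard)
            )
            rates.append(ev.rate)
        cum = np.cumsum(rates)
        entry = (tuple(cached), cum, float(cum[-1]) if len(cum) else 0.0)
        self._cache[sigma] = entry
        return entry


@dataclass
class Trajectory:
    """Event log of one simulated cargo run."""

    seed: int
    times: list[float] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)
    sites: list[int] = field(default_factory=list)          # absolute site
    states: list[RelativeConfiguration] = field(default_factory=list)
    displacements: list[float] = field(default_factory=list)
    lost: bool = False
    loss_time: float | None = None
    horizon: float = 0.0

    @property
    def run_length(self) -> float:
        return float(sum(self.displacements))

    @property
    def final_state(self) -> RelativeConfiguration:
        return self.states[-1] if self.states else None


DEFAULT_Z0 = AbsoluteConfiguration((0,), (1,))


def simulate(Z0: AbsoluteConfiguration, t_end: float, seed: int,
             p: ModelParameters, cache: _EventCache | None = None,
             record: bool = True) -> Trajectory:
    """Simulate the absolute chain from Z0 until cargo loss or t_end.

    Exponential waiting times from the total outflow rate; the event is
    chosen proportionally to its rate.  Fully reproducible from seed.
    """
    if Z0.is_empty:
        raise ValueError("cannot simulate from the lost-cargo state")
    if cache is None:
        cache = _EventCache(p)
    rng = np.random.default_rng(seed)
    sigma = project(Z0)
    rear = Z0.rearguard
    t = 0.0
    traj = Trajectory(seed=seed, horizon=t_end)
    traj.states.append(sigma)
    while True:
        events, cum, total = cache.get(sigma)
        if total <= 0.0:
            break  # frozen configuration (possible only under a hard cap)
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        u = rng.random() * total
        idx = int(np.searchsorted(cum, u, side="right"))
        idx = min(idx, len(events) - 1)
        ev = events[idx]
        if record:
            traj.times.append(t)
            traj.kinds.append(ev.kind)
            traj.sites.append(rear + ev.site_offset)
            traj.displacements.append(ev.displacement)
        else:
            traj.displacements.append(ev.displacement)
        if ev.target.is_empty:
            traj.lost = True
            traj.loss_time = t
            if record:
                traj.states.append(ev.target)
            break
        rear += ev.rear_shift
        sigma = ev.target
        if record:
            traj.states.append(sigma)
    return traj


def run_length_samples(p: ModelParameters, n_traj: int, seed: int,
                       Z0: AbsoluteConfiguration = DEFAULT_Z0,
                       t_end: float = 1e6) -> np.ndarray:
    """Cargo run lengths (nm) of n_traj independent runs to absorption."""
    cache = _EventCache(p)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_traj)
    out = np.empty(n_traj)
    for i, s in enumerate(seeds):
        traj = simulate(Z0, t_end, int(s), p, cache=cache, record=False)
        out[i] = sum(traj.displacements)
    return out


def states_at(p: ModelParameters, t: float, n_traj: int, seed: int,
              Z0: AbsoluteConfiguration = DEFAULT_Z0) -> list[RelativeConfiguration]:
    """Relative configuration of each of n_traj runs at time t
    (the lost-cargo state if absorbed before t)."""
    cache = _EventCache(p)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_traj)
    out = []
    for s in seeds:
        traj = simulate(Z0, t, int(s), p, cache=cache, record=True)
        out.append(traj.states[-1])
    return out


def empirical_distribution(states: list[RelativeConfiguration],
                           space: StateSpace) -> np.ndarray:
    """Frequency vector over the state space from sampled configurations."""
    P = np.zeros(space.size)
    for s in states:
        P[space.index(s)] += 1.0
    return P / len(states)


def step_displacement_samples(p: ModelParameters, n_events: int, seed: int,
                              burn_in: float = 3.0, horizon: float = 6.0,
                              Z0: AbsoluteConfiguration = DEFAULT_Z0) -> np.ndarray:
    """Nonzero cargo-equilibrium displacements observed per event in the
    stationary regime (events after burn_in from surviving runs)."""
    cache = _EventCache(p)
    ss = np.random.SeedSequence(seed)
    samples: list[float] = []
    batch = 0
    while len(samples) < n_events:
        seeds = ss.generate_state(64)
        for s in seeds:
            traj = simulate(Z0, horizon, int(s), p, cache=cache, record=True)
            for t_ev, d in zip(traj.times, traj.displacements):
                if t_ev >= burn_in and abs(d) > 5e-7:
                    samples.append(d)
            if len(samples) >= n_events:
                break
        batch += 1
        if batch > 10_000:
            raise RuntimeError("failed to collect the requested number of events")
    return np.array(samples[:n_events])


def max_observed_span(p: ModelParameters, n_events: int, seed: int,
                      Z0: AbsoluteConfiguration = DEFAULT_Z0,
                      horizon: float = 1e6) -> int:
    """Largest extent (sites) seen across at least n_events simulated
    events, restarting runs on absorption."""
    cache = _EventCache(p)
    ss = np.random.SeedSequence(seed)
    seen = 0
    worst = 1
    while seen < n_events:
        seeds = ss.generate_state(16)
        for s in seeds:
            traj = simulate(Z0, horizon, int(s), p, cache=cache, record=True)
            seen += len(traj.times)
            for st in traj.states:
                worst = max(worst, st.span)
            if seen >= n_events:
                break
    return worst
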