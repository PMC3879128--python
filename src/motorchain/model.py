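"""Facade tying parameters, state space, transition table and generator.

``MotorEnsembleModel`` resolves the extent bound, enumerates the
relative configurations, builds the projected transition table and the
master-equation generator, and exposes the observables.  The a priori
extent bound from the stall condition is *verified* here: the builder
checks that no transition leaves the enumerated space and enlarges the
extent until the chain is closed (the physical stall/attachment bounds
guarantee termination).  With ``n_cap`` set the space is truncated
instead and out-of-space events are dropped and counted.
"""

from __future__ import annotations

import math

import numpy as np

from . import kinetics, observables, solver
from .parameters import ModelParameters
from .state_space import (
    RelativeConfiguration,
    StateSpace,
    canonical_representative,
    enumerate_states,
    max_extent,
)
from .mechanics import cargo_equilibrium
from .kinetics import RelativeTransitionTable, site_step_rate, attachment_events


def _max_target_span(sigma: RelativeConfiguration, p: ModelParameters) -> int:
    """Largest extent reachable in one event from sigma.

    Only a vanguard step (span+1, suppressed at stall) or an attachment
    outside the current span can increase the extent, so only those are
    probed — the full displacement bookkeeping is not needed here.
    """
    Z = canonical_representative(sigma)
    eq = cargo_equilibrium(Z, p)
    span = Z.span
    best = span
    if site_step_rate(Z, Z.vanguard, p, eq) > 0.0:
        best = max(best, span + 1)
    for ev in attachment_events(Z, p, eq):
        t = ev.target
        best = max(best, t.span)
    return best


def closed_extent(p: ModelParameters) -> tuple[int, bool]:
    """Extent bound verified to close the transition map.

    Starts from the a priori stall-condition bound and grows it until
    no state can reach beyond it.  Returns (n, truncated).
    """
    bound = max_extent(p)
    if bound.truncated:
        return bound.n, True
    n = bound.n
    checked_to = 0
    while True:
        space = enumerate_states(p.m_bar, n)
        worst = n
        for sigma in space.nonempty():
            if sigma.span <= checked_to:
                continue
            worst = max(worst, _max_target_span(sigma, p))
        if worst <= n:
            return n, False
        checked_to = n
        n = worst
        if p.n_cap is not None and n >= p.n_cap:
            return p.n_cap, True


class MotorEnsembleModel:
    """Exact finite Markov chain of a motor ensemble under load.

    Builds the closed state space, the projected transition table and
    the sparse generator for the given parameters, then delegates to
    the solver and observables layers.
    """

    def __init__(self, params: ModelParameters):
        self.params = params
        self.n, self.truncated = closed_extent(params)
        self.space: StateSpace = enumerate_states(params.m_bar, self.n)
        if self.truncated:
            # count dropped events for the manifest
            self.table, self.dropped = self._build_capped_table()
        else:
            self.table: RelativeTransitionTable = kinetics.build_table(
                self.space, params
            )
            self.dropped = 0
        self.generator = solver.build_generator(self.space, self.table)

    def _build_capped_table(self):
        # recompute without the cap so suppressed events can be counted
        p_uncapped = self.params.replace(n_cap=None)
        rows = {}
        dropped = 0
        for sigma in self.space.nonempty():
            groups = kinetics.relative_rates(sigma, p_uncapped)
            kept = []
            for g in groups:
                if not g.target.is_empty and g.target.span > self.n:
                    dropped += len(g.events)
                    continue
                kept.append(g)
            rows[sigma] = tuple(kept)
        return kinetics.RelativeTransitionTable(rows), dropped

    # --- state-space conveniences -------------------------------------
    @property
    def size(self) -> int:
        return self.space.size

    def state_index(self, sigma: RelativeConfiguration | str) -> int:
        if isinstance(sigma, str):
            sigma = RelativeConfiguration.from_string(sigma)
        return self.space.index(sigma)

    # --- solver delegation --------------------------------------------
    def initial_distribution(self, warmup: float = 1.0) -> np.ndarray:
        return solver.initial_distribution(self.generator, warmup=warmup)

    def propagate(self, P0: np.ndarray, dt: float) -> np.ndarray:
        return solver.propagate(P0, dt, self.generator)

    def conditional(self, P: np.ndarray) -> np.ndarray:
        return solver.conditional_not_lost(P, self.generator)

    def quasi_stationary(self) -> np.ndarray:
        return solver.quasi_stationary(self.generator)

    # --- observables ---------------------------------------------------
    def expected_engaged(self, dist: np.ndarray) -> float:
        return observables.expected_engaged(dist, self.space)

    def mean_velocity(self, dist: np.ndarray) -> float:
        return observables.mean_velocity(dist, self.table, self.space)

    def average_run_length(self, P0: np.ndarray | None = None) -> float:
        if P0 is None:
            P0 = self.initial_distribution()
        return observables.average_run_length(P0, self.generator, self.table)

    def step_size_distribution(self, dist: np.ndarray | None = None):
        if dist is None:
            dist = self.quasi_stationary()
        return observables.step_size_distribution(dist, self.table, self.space)
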