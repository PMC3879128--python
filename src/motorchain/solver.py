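"""Generator assembly and exact master-equation solution.

The generator A follows the column convention dP/dt = A P: the
off-diagonal A[j, i] is the projected rate from state i into state j,
each diagonal balances its column to zero, and the lost-cargo state is
absorbing (zero column).  Q is the substochastic restriction of A to
the non-empty states; its spectrum governs survival and the
quasi-stationary (conditional steady-state) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .state_space import RelativeConfiguration, StateSpace
from .kinetics import RelativeTransitionTable

_DENSE_EIG_LIMIT = 3000


class SolverError(RuntimeError):
    pass


@dataclass
class Generator:
    A: sp.csc_matrix          # N x N rate matrix, dP/dt = A P
    Q: sp.csc_matrix          # (N-1) x (N-1) restriction to non-empty states
    space: StateSpace

    @property
    def size(self) -> int:
        return self.A.shape[0]


def build_generator(space: StateSpace, table: RelativeTransitionTable) -> Generator:
    """Assemble the sparse generator from the transition table.

    Self-transition classes (same relative configuration before and
    after, e.g. a lone motor stepping) cancel between the off-diagonal
    and the diagonal and are therefore omitted from both.
    """
    N = space.size
    rows, cols, vals = [], [], []
    diag = np.zeros(N)
    for sigma in space.nonempty():
        i = space.index(sigma)
        for g in table.groups(sigma):
            if g.rate < 0:
                raise SolverError(f"negative rate {g.rate} on {sigma} -> {g.target}")
            j = space.index(g.target)
            if j == i:
                continue  # self transitions cancel in the generator
            rows.append(j)
            cols.append(i)
            vals.append(g.rate)
            diag[i] -= g.rate
    A = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsc()
    A += sp.diags(diag).tocsc()
    Q = A[: N - 1, : N - 1].tocsc()
    return Generator(A=A, Q=Q, space=space)


_DENSE_EXPM_LIMIT = 1500


def propagate(P0: np.ndarray, dt: float, G: Generator) -> np.ndarray:
    """P(t0 + dt) = exp(A dt) P(t0) via matrix-exponential action.

    Krylov-free expm_multiply costs O(||A|| dt) matvecs, so for long
    horizons at moderate dimension the dense scaling-and-squaring
    exponential (O(log ||A dt||) matrix products) is used instead.
    """
    if dt < 0:
        raise SolverError(f"negative propagation time {dt}")
    if dt == 0:
        return np.array(P0, dtype=float, copy=True)
    P0 = np.asarray(P0, dtype=float)
    N = G.size
    rate_scale = float(np.abs(G.A.diagonal()).max()) * dt
    if N <= _DENSE_EXPM_LIMIT and rate_scale > 200.0:
        return scipy.linalg.expm((G.A * dt).toarray()) @ P0
    return spla.expm_multiply(G.A * dt, P0)


def initial_distribution(G: Generator, warmup: float = 1.0) -> np.ndarray:
    """The reference initialization: one motor engaged at t = -warmup,
    conditioned on the cargo surviving until t = 0.

    Propagates the point mass on "M" under the loss-free restriction Q
    for ``warmup`` seconds and renormalizes; the lost-cargo entry is 0.
    """
    space = G.space
    N = space.size
    iM = space.index(RelativeConfiguration.from_string("M"))
    v = np.zeros(N - 1)
    v[iM] = 1.0
    if warmup > 0:
        v = spla.expm_multiply(G.Q * warmup, v)
    total = v.sum()
    if total <= 0:
        raise SolverError("warm-up propagation lost all probability mass")
    P = np.zeros(N)
    P[: N - 1] = v / total
    return P


def conditional_not_lost(P: np.ndarray, G: Generator) -> np.ndarray:
    """Distribution over non-empty states given the cargo is not lost."""
    N = G.size
    P = np.asarray(P, dtype=float)
    surv = P[: N - 1].sum()
    if surv <= 0:
        raise SolverError("conditioning on survival with zero survival probability")
    return P[: N - 1] / surv


def reachable_from_single_motor(G: Generator) -> np.ndarray:
    """Indices of non-empty states reachable from "M" in the transition graph."""
    space = G.space
    iM = space.index(RelativeConfiguration.from_string("M"))
    # edge i -> j iff A[j, i] != 0; BFS wants row-to-column adjacency
    adj = (G.Q.T != 0).tocsr()
    order = csgraph.breadth_first_order(adj, iM, directed=True,
                                        return_predecessors=False)
    return np.sort(order)


def quasi_stationary(G: Generator) -> np.ndarray:
    """Conditional steady state over non-empty states.

    The eigenvector of Q (restricted to states reachable from "M") for
    the eigenvalue of largest real part, normalized non-negative and
    summing to one; unreachable states carry exactly zero.
    """
    N = G.size
    reach = reachable_from_single_motor(G)
    QR = G.Q[np.ix_(reach, reach)].tocsc()
    n = QR.shape[0]
    if n == 1:
        pi_r = np.array([1.0])
    elif n <= _DENSE_EIG_LIMIT:
        w, v = scipy.linalg.eig(QR.toarray())
        k = int(np.argmax(w.real))
        pi_r = v[:, k].real
    else:
        try:
            w, v = spla.eigs(QR, k=1, sigma=0.0, which="LM")
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise SolverError(f"quasi-stationary eigensolve failed: {exc}") from exc
        pi_r = v[:, 0].real
    if pi_r.sum() < 0:
        pi_r = -pi_r
    if pi_r.min() < -1e-8 * max(1.0, pi_r.max()):
        raise SolverError("quasi-stationary eigenvector has significant negative entries")
    pi_r = np.clip(pi_r, 0.0, None)
    pi_r /= pi_r.sum()
    pi = np.zeros(N - 1)
    pi[reach] = pi_r
    return pi


def decay_rate(G: Generator) -> float:
    """Absorption (survival-decay) rate: minus the top eigenvalue of Q
    on the reachable class."""
    reach = reachable_from_single_motor(G)
    QR = G.Q[np.ix_(reach, reach)]
    n = QR.shape[0]
    if n == 1:
        return float(-QR.toarray()[0, 0])
    if n <= _DENSE_EIG_LIMIT:
        w = scipy.linalg.eigvals(QR.toarray())
        return float(-np.max(w.real))
    w = spla.eigs(QR.tocsc(), k=1, sigma=0.0, which="LM",
                  return_eigenvectors=False)
    return float(-w[0].real)
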