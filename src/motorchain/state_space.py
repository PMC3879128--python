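"""Absolute and relative motor configurations and their enumeration.

An *absolute configuration* records how many motors are engaged at each
site of the microtubule lattice (site k sits at ``a_k = k*d_s``).  A
*relative configuration* forgets the absolute position and keeps only
the occupancy pattern starting from the rearguard (hindmost) motor; it
is written in a two-symbol string notation, e.g. ``"M||MM||M"`` for a
rearguard motor, two motors three sites ahead and one motor six sites
ahead.  The empty configuration (no motor engaged, cargo lost) is the
absorbing state of the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .parameters import ModelParameters

EMPTY_STRING = "-"  # rendering of the lost-cargo configuration


class StateSpaceError(ValueError):
    """Raised for invalid configurations or an oversized enumeration."""


@dataclass(frozen=True)
class RelativeConfiguration:
    """Occupancy counts per site, starting at the rearguard site.

    ``counts`` is empty for the lost-cargo state; otherwise its first
    and last entries are >= 1 (rearguard and vanguard sites occupied).
    """

    counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        c = self.counts
        if c:
            if c[0] < 1 or c[-1] < 1 or any(x < 0 for x in c):
                raise StateSpaceError(f"invalid relative configuration counts {c}")

    @property
    def motor_count(self) -> int:
        return sum(self.counts)

    @property
    def span(self) -> int:
        """Number of lattice sites spanned, rearguard to vanguard inclusive."""
        return len(self.counts)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    def __str__(self) -> str:
        if not self.counts:
            return EMPTY_STRING
        return "|".join("M" * c for c in self.counts)

    @classmethod
    def from_string(cls, s: str) -> "RelativeConfiguration":
        s = s.strip()
        if s in ("", EMPTY_STRING):
            return cls(())
        counts = []
        for chunk in s.split("|"):
            if set(chunk) - {"M"}:
                raise StateSpaceError(f"invalid configuration string {s!r}")
            counts.append(len(chunk))
        return cls(tuple(counts))


EMPTY = RelativeConfiguration(())


@dataclass(frozen=True)
class AbsoluteConfiguration:
    """Motor counts on integer lattice sites (finite support).

    Stored as parallel sorted tuples of occupied site indices and their
    (strictly positive) motor counts.
    """

    sites: tuple[int, ...] = ()
    counts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.counts):
            raise StateSpaceError("sites and counts must have equal length")
        if any(c < 1 for c in self.counts):
            raise StateSpaceError("occupied sites must carry counts >= 1")
        if any(a >= b for a, b in zip(self.sites, self.sites[1:])):
            raise StateSpaceError("sites must be strictly increasing")

    @classmethod
    def from_occupancy(cls, occupancy: dict[int, int]) -> "AbsoluteConfiguration":
        items = sorted((k, z) for k, z in occupancy.items() if z != 0)
        return cls(tuple(k for k, _ in items), tuple(z for _, z in items))

    @property
    def occupancy(self) -> dict[int, int]:
        return dict(zip(self.sites, self.counts))

    @property
    def motor_count(self) -> int:
        return sum(self.counts)

    @property
    def is_empty(self) -> bool:
        return not self.sites

    @property
    def rearguard(self) -> int:
        return self.sites[0]

    @property
    def vanguard(self) -> int:
        return self.sites[-1]

    @property
    def span(self) -> int:
        """Sites spanned inclusive of rearguard and vanguard."""
        if not self.sites:
            return 0
        return self.sites[-1] - self.sites[0] + 1

    def positions(self, p: ModelParameters) -> tuple[float, ...]:
        """Physical positions a_k = k*d_s of the occupied sites."""
        return tuple(k * p.d_s for k in self.sites)

    def shift(self, alpha: int) -> "AbsoluteConfiguration":
        return AbsoluteConfiguration(
            tuple(k + alpha for k in self.sites), self.counts
        )


ABS_EMPTY = AbsoluteConfiguration((), ())


def project(Z: AbsoluteConfiguration) -> RelativeConfiguration:
    """Projection onto the relative configuration (translation invariant)."""
    if Z.is_empty:
        return EMPTY
    counts = [0] * Z.span
    base = Z.rearguard
    for k, z in zip(Z.sites, Z.counts):
        counts[k - base] = z
    return RelativeConfiguration(tuple(counts))


def canonical_representative(sigma: RelativeConfiguration) -> AbsoluteConfiguration:
    """The absolute configuration with this pattern and rearguard at site 0."""
    if sigma.is_empty:
        raise StateSpaceError("the lost-cargo configuration has no representative")
    occ = {k: z for k, z in enumerate(sigma.counts) if z > 0}
    return AbsoluteConfiguration.from_occupancy(occ)


@dataclass(frozen=True)
class ExtentBound:
    n: int
    truncated: bool
    theoretical: int


def max_extent(p: ModelParameters) -> ExtentBound:
    """A priori bound on the sites spanned by an engaged ensemble.

    The bound follows from the stall condition: the vanguard motor
    cannot step once its load reaches F_s, and attachments happen
    within l0 of the cargo; thermal wander of the cargo contributes
    6*sigma_th.  The returned value seeds the state-space size; the
    model builder additionally verifies (and if necessary enlarges)
    it so that no transition leaves the enumerated space.
    """

    per_site = p.k_el * p.d_s
    term1 = math.ceil((p.m_bar * p.F_s - p.F_load) / per_site) + 1
    term2 = math.ceil(
        p.F_load / per_site + 2.0 * p.l0 / p.d_s + 6.0 * p.sigma_th / p.d_s
    )
    n = max(term1, term2)
    if n < 1:
        raise StateSpaceError(f"non-positive extent bound n={n}")
    if p.n_cap is not None and p.n_cap < n:
        return ExtentBound(p.n_cap, True, n)
    return ExtentBound(n, False, n)


def count_states(m_bar: int, n: int) -> int:
    """Closed-form number of relative configurations (incl. lost cargo).

    1 + sum_{m=1..m_bar} C(n+m-2, m-1): multisets of m indistinguishable
    motors on at most n sites with the rearguard site occupied.
    """
    if m_bar < 1 or n < 1:
        raise StateSpaceError("m_bar and n must be >= 1")
    return 1 + sum(math.comb(n + m - 2, m - 1) for m in range(1, m_bar + 1))


def _compositions(total: int, length: int) -> Iterator[tuple[int, ...]]:
    """Occupancy tuples of given length summing to total, first and last >= 1,
    in lexicographic order."""
    if length == 1:
        yield (total,)
        return

    def rec(prefix: list[int], remaining: int, slots: int) -> Iterator[tuple[int, ...]]:
        if slots == 1:  # last slot, must be >= 1
            if remaining >= 1:
                yield tuple(prefix + [remaining])
            return
        lo = 1 if not prefix else 0
        for c in range(lo, remaining - 1 + 1):  # leave >=1 for the last slot
            yield from rec(prefix + [c], remaining - c, slots - 1)

    yield from rec([], total, length)


MAX_ENUMERATION = 5_000_000


@dataclass(frozen=True)
class StateSpace:
    """Ordered list of every relative configuration plus the absorbing state.

    Order is graded: by motor count, then span, then lexicographic
    occupancy; the lost-cargo state is last.  The order is deterministic
    so generator matrices are bit-reproducible.
    """

    states: tuple[RelativeConfiguration, ...]
    m_bar: int
    n: int

    @property
    def size(self) -> int:
        return len(self.states)

    @property
    def empty_index(self) -> int:
        return len(self.states) - 1

    def index(self, sigma: RelativeConfiguration) -> int:
        return self._index[sigma]

    def __contains__(self, sigma: RelativeConfiguration) -> bool:
        return sigma in self._index

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.states)}
        )

    def nonempty(self) -> tuple[RelativeConfiguration, ...]:
        return self.states[:-1]


def enumerate_states(m_bar: int, n: int) -> StateSpace:
    """Enumerate every relative configuration with up to m_bar motors
    spanning at most n sites; the absorbing (empty) state goes last."""
    total = count_states(m_bar, n)
    if total > MAX_ENUMERATION:
        raise StateSpaceError(
            f"state space would hold {total} states; set n_cap to truncate"
        )
    states: list[RelativeConfiguration] = []
    for m in range(1, m_bar + 1):
        for length in range(1, min(n, m if m == 1 else n) + 1):
            for counts in _compositions(m, length):
                states.append(RelativeConfiguration(counts))
    states.append(EMPTY)
    if len(states) != total:
        raise StateSpaceError(
            f"enumeration produced {len(states)} states, expected {total}"
        )
    return StateSpace(tuple(states), m_bar, n)
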