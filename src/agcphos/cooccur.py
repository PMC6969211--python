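"""Substitution proportions and set-overlap (Euler) summaries.

Summarises per-kinase site calls into the counts behind the questions the
analysis asks: how often is the AL or HM phospho-site phosphorylatable,
phosphomimetic, something else, or missing; and does a phosphorylatable AL
co-occur with a basic residue at a phosphate-coordination site?  A Fisher
exact test (implemented from the hypergeometric mass) quantifies the
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Callable

from .motifs import KinaseRecord, SiteKind, State


@dataclass
class StateCounts:
    site_kind: SiteKind
    counts: dict[State, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportion(self, state: State) -> float:
        return self.counts.get(state, 0) / self.total


@dataclass(frozen=True)
class OverlapSummary:
    """Counts for a two-set Euler diagram over a fixed universe of kinases."""

    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    n_both: int
    n_neither: int

    @property
    def universe(self) -> int:
        return self.n_a + self.n_b - self.n_both + self.n_neither

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_a, self.n_b):
            raise ValueError("intersection larger than a set")
        if min(self.n_a, self.n_b, self.n_both, self.n_neither) < 0:
            raise ValueError("negative count")

    def contingency(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """2x2 table (in A & in B, in A only; in B only, in neither)."""
        return (
            (self.n_both, self.n_a - self.n_both),
            (self.n_b - self.n_both, self.n_neither),
        )


def state_proportions(
    records: list[KinaseRecord], site_kind: SiteKind
) -> StateCounts:
    """Count residue states over all records for the AL or HM site."""
    if not records:
        raise ValueError("no records")
    counts: dict[State, int] = {}
    for rec in records:
        call = rec.al_call if site_kind is SiteKind.AL else rec.hm_call
        counts[call.state] = counts.get(call.state, 0) + 1
    return StateCounts(site_kind=site_kind, counts=counts)


def euler_overlap(
    records: list[KinaseRecord],
    predicate_a: Callable[[KinaseRecord], bool],
    predicate_b: Callable[[KinaseRecord], bool],
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapSummary:
    """Exact overlap counts of two predicate-defined kinase sets."""
    n_a = n_b = n_both = n_neither = 0
    for rec in records:
        a, b = predicate_a(rec), predicate_b(rec)
        n_a += a
        n_b += b
        n_both += a and b
        n_neither += (not a) and (not b)
    return OverlapSummary(name_a, name_b, n_a, n_b, n_both, n_neither)


# Standard predicates used throughout the analysis.
def al_phosphorylatable(rec: KinaseRecord) -> bool:
    return rec.al_call.state is State.PHOSPHORYLATABLE


def triad_basic(site: str) -> Callable[[KinaseRecord], bool]:
    def pred(rec: KinaseRecord) -> bool:
        return any(t.site == site and t.is_basic for t in rec.triad)

    return pred


def fisher_exact(table: tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding that of the observed table (the standard
    two-sided convention).  Written out from the hypergeometric mass so the
    convention is explicit; a small numerical slack (1e-9, relative) guards
    the <= comparison against rounding.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return min(
        1.0,
        sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9)),
    )
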