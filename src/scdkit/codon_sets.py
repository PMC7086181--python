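"""Enumeration of unordered tricodon sets and compositional matching.

The stop codons {TAA, TAG, TGA} have a distinctive composition: 2 of the
9 nucleotides are G/C (GC content 0.222) and 6 of 9 are purines (0.667).
To ask whether a depletion is specific to the stop codons rather than to
that composition, the full universe of unordered sets of three distinct
codons is enumerated and filtered to compositional matches of the stop
set.  The universe holds 64x63x62/3! = 41,664 sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

from scipy.stats import binomtest

from .density import STOP_CODONS

NUCLEOTIDES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)
_PURINES = frozenset("AG")
_GC = frozenset("GC")


def codons_can_overlap(x: str, y: str) -> bool:
    """True if two codons can physically overlap in a sequence.

    Checks whether the length-1 or length-2 suffix of either codon equals
    the corresponding prefix of the other (both orientations; x may equal
    y, so self-overlap like AAA/AAA counts).
    """
    for k in (1, 2):
        if x[-k:] == y[:k] or y[-k:] == x[:k]:
            return True
    return False


@dataclass(frozen=True)
class CodonTriple:
    """An unordered set of three distinct codons, stored sorted."""

    codons: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(set(self.codons)) != 3:
            raise ValueError("CodonTriple requires 3 distinct codons")
        object.__setattr__(self, "codons", tuple(sorted(self.codons)))

    @property
    def gc_count(self) -> int:
        """G+C nucleotides over all 9 positions (stop set: 2)."""
        return sum(1 for c in self.codons for b in c if b in _GC)

    @property
    def purine_count(self) -> int:
        """A+G nucleotides over all 9 positions (stop set: 6)."""
        return sum(1 for c in self.codons for b in c if b in _PURINES)

    @property
    def contains_stop(self) -> bool:
        return any(c in STOP_CODONS for c in self.codons)

    @property
    def has_internal_overlap(self) -> bool:
        """True if any member can overlap a *different* member of the set.

        All ordered pairs of distinct members are checked; a codon's
        ability to overlap itself is not counted.  The stop set has no
        internal overlap.
        """
        return any(
            codons_can_overlap(a, b)
            for a, b in itertools.permutations(self.codons, 2)
        )


STOP_SET = CodonTriple(STOP_CODONS)


def enumerate_tricodon_sets() -> list[CodonTriple]:
    """All 41,664 unordered sets of three distinct codons, stops included."""
    return [CodonTriple(c) for c in itertools.combinations(ALL_CODONS, 3)]


def filter_sets(
    sets: Iterable[CodonTriple],
    gc_match: Optional[int] = None,
    purine_match: Optional[int] = None,
    exclude_stop_members: bool = False,
    require_no_overlap: bool = False,
) -> list[CodonTriple]:
    """Retain tricodon sets satisfying the conjunction of requested criteria.

    Against the full enumeration the stop-set-matched counts are:
    gc_match=2 -> 2,879; purine_match=6 -> 6,856; both -> 473;
    gc_match=2 without stop members -> 2,121; gc_match=2 and
    non-overlapping -> 131.
    """
    for crit, name in ((gc_match, "gc_match"), (purine_match, "purine_match")):
        if crit is not None and not 0 <= crit <= 9:
            raise ValueError(f"{name} must be in [0, 9], got {crit}")
    out = []
    for s in sets:
        if gc_match is not None and s.gc_count != gc_match:
            continue
        if purine_match is not None and s.purine_count != purine_match:
            continue
        if exclude_stop_members and s.contains_stop:
            continue
        if require_no_overlap and s.has_internal_overlap:
            continue
        out.append(s)
    return out


@dataclass(frozen=True)
class MatchedComparison:
    """How a target set's fold enrichment ranks among matched controls."""

    n_greater: int
    n_total: int
    p_binomial: float

    @property
    def fraction(self) -> float:
        return self.n_greater / self.n_total


def compare_against_matched(
    target: CodonTriple,
    matched: Sequence[CodonTriple],
    fe_of: Mapping[CodonTriple, float] | Callable[[CodonTriple], float],
) -> MatchedComparison:
    """Count matched sets whose FE strictly exceeds the target's.

    The one-tailed binomial p (null success probability 0.5) asks whether
    more than half of the compositionally matched controls are less
    depleted than the target.
    """
    if not matched:
        raise ValueError("matched list must be nonempty")
    get = fe_of.__getitem__ if hasattr(fe_of, "__getitem__") else fe_of
    target_fe = get(target)
    n_greater = sum(1 for s in matched if get(s) > target_fe)
    test = binomtest(n_greater, len(matched), p=0.5, alternative="greater")
    return MatchedComparison(n_greater, len(matched), test.pvalue)


def stop_matched_control_sets(
    universe: Optional[Sequence[CodonTriple]] = None,
) -> dict[str, list[CodonTriple]]:
    """The compositionally matched control groups for the stop-codon set.

    Control groups anchored on the reference set's GC content exclude
    the reference set itself — it cannot serve as its own control in an
    FE-ranking comparison — giving 2,879 GC-matched sets, 473 matched on
    both GC and purine content, 2,121 GC-matched sets free of stop-codon
    members and 131 GC-matched sets with no internal overlap.  The
    purine-only group is the raw filter (6,856 sets, reference
    included).
    """
    if universe is None:
        universe = enumerate_tricodon_sets()

    def drop_ref(sets: list[CodonTriple]) -> list[CodonTriple]:
        return [s for s in sets if s != STOP_SET]

    return {
        "gc_matched": drop_ref(filter_sets(universe, gc_match=2)),
        "purine_matched": filter_sets(universe, purine_match=6),
        "gc_and_purine_matched": drop_ref(
            filter_sets(universe, gc_match=2, purine_match=6)
        ),
        "gc_matched_no_stop_members": drop_ref(
            filter_sets(universe, gc_match=2, exclude_stop_members=True)
        ),
        "gc_matched_non_overlapping": drop_ref(
            filter_sets(universe, gc_match=2, require_no_overlap=True)
        ),
    }


def summary_counts() -> dict[str, int]:
    """Universe size plus the matched control-group sizes."""
    universe = enumerate_tricodon_sets()
    counts = {"all_tricodon_sets": len(universe)}
    counts.update(
        {name: len(group) for name, group in stop_matched_control_sets(universe).items()}
    )
    return counts
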