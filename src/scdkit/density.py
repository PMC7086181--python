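"""Coverage-based motif and codon densities.

The central metric of the package: the fraction of a sequence's positions
covered by at least one occurrence of any motif in a query set, with each
position counted once regardless of how many occurrences overlap it.  The
stop-codon density (SCD) is this metric for the tricodon set
{TAA, TAG, TGA}, scanned in every frame.

Densities are bounded by 0 (no position matches) and 1 (every position
lies inside a hit), which makes them comparable across sequences and
query sets of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STOP_CODONS: tuple[str, str, str] = ("TAA", "TAG", "TGA")

_ALPHABET = frozenset("ACGT")


def validate_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase ``seq`` and reject anything outside the {A,C,G,T} alphabet."""
    if not seq:
        raise ValueError(f"empty {context}")
    up = seq.upper()
    if not _ALPHABET.issuperset(up):
        bad = sorted(set(up) - _ALPHABET)
        raise ValueError(f"{context} contains noncanonical characters: {bad}")
    return up


def _as_motif_list(motifs) -> list[str]:
    # CodonTriple and similar containers expose .codons; plain iterables of
    # strings are accepted as-is.
    if hasattr(motifs, "codons"):
        return list(motifs.codons)
    return list(motifs)


@dataclass(frozen=True)
class CoverageMask:
    """Positions of a sequence covered by at least one motif occurrence."""

    sequence_length: int
    covered: frozenset[int]

    def __post_init__(self) -> None:
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if self.covered and not all(
            0 <= p < self.sequence_length for p in self.covered
        ):
            raise ValueError("covered positions out of range")

    @property
    def covered_count(self) -> int:
        return len(self.covered)

    def uncovered_runs(self) -> list[tuple[int, int]]:
        """Maximal half-open intervals of uncovered positions, in order."""
        runs: list[tuple[int, int]] = []
        start = None
        for i in range(self.sequence_length):
            if i in self.covered:
                if start is not None:
                    runs.append((start, i))
                    start = None
            elif start is None:
                start = i
        if start is not None:
            runs.append((start, self.sequence_length))
        return runs


@dataclass(frozen=True)
class DensityResult:
    """A covered-position count, the total length scanned, and their ratio."""

    covered_count: int
    sequence_length: int

    @property
    def density(self) -> float:
        return self.covered_count / self.sequence_length


def find_hits(seq: str, motifs: Iterable[str]) -> CoverageMask:
    """Scan ``seq`` for every occurrence of every motif at every offset.

    Overlapping occurrences — of the same motif with itself or between
    motifs — are merged at the position level, so each covered nucleotide
    is recorded once.
    """
    seq = validate_sequence(seq)
    covered: set[int] = set()
    for motif in _as_motif_list(motifs):
        motif = motif.upper()
        k = len(motif)
        i = seq.find(motif)
        while i != -1:
            covered.update(range(i, i + k))
            i = seq.find(motif, i + 1)
    return CoverageMask(len(seq), frozenset(covered))


def motif_density(seq: str, motifs: Iterable[str]) -> DensityResult:
    """Coverage density of a motif set in one sequence."""
    mask = find_hits(seq, motifs)
    return DensityResult(mask.covered_count, mask.sequence_length)


def pooled_density(seqs: Sequence[str], motifs: Iterable[str]) -> DensityResult:
    """Aggregate density over a sequence set.

    Covered counts and lengths are summed before division — one statistic
    for the pooled nucleotides, not a mean of per-sequence densities.
    """
    if not seqs:
        raise ValueError("pooled_density requires at least one sequence")
    motif_list = _as_motif_list(motifs)
    covered = 0
    length = 0
    for seq in seqs:
        mask = find_hits(seq, motif_list)
        covered += mask.covered_count
        length += mask.sequence_length
    return DensityResult(covered, length)


def scd(seq: str) -> float:
    """Stop-codon density of one sequence (any-frame, overlap-once)."""
    return motif_density(seq, STOP_CODONS).density


def pooled_scd(seqs: Sequence[str]) -> float:
    """Pooled stop-codon density over a sequence set."""
    return pooled_density(seqs, STOP_CODONS).density


def mask_and_split(seq: str, motifs: Iterable[str]) -> list[str]:
    """Remove every position matching a motif and return the remaining parts.

    Parts interrupted by a hit are kept separate rather than concatenated,
    so no new motif occurrence can be created across a removed hit.  A
    fully covered sequence yields an empty list.
    """
    mask = find_hits(seq, motifs)
    seq = seq.upper()
    return [seq[a:b] for a, b in mask.uncovered_runs()]


def motif_contains_stop(motif: str) -> bool:
    """True if TAA, TAG or TGA occurs at any offset of ``motif``.

    Motifs shorter than a codon cannot contain one and return False.
    """
    motif = motif.upper()
    return any(stop in motif for stop in STOP_CODONS)
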