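"""Dinucleotide-matched pseudo-motif sets and motif-level nulls.

A motif set (for instance 84 splice-enhancer hexamers) is summarised by
the counts of all overlapping dinucleotides across its motifs — the
motif GAAGTA contributes GA, AA, AG, GT and TA.  Pseudo-motif sets of
identical size and length multiset are then built by concatenating
dinucleotides sampled independently from those frequencies (with one
nucleotide, drawn from the mononucleotide counts, appended to odd-length
motifs).  Densities of a query codon set in thousands of such pseudo
sets form the null for the density in the real motifs, controlling for
the motifs' own nucleotide content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .density import pooled_density
from .sequence_null import iteration_rngs

DINUCLEOTIDES: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product("ACGT", repeat=2)
)


class SaturationError(RuntimeError):
    """Raised when a profile cannot yield enough distinct pseudo-motifs."""


@dataclass(frozen=True)
class DinucleotideProfile:
    """Dinucleotide and mononucleotide counts of a motif set."""

    counts: dict[str, int]
    nucleotide_counts: dict[str, int]

    @property
    def dinucleotide_probs(self) -> np.ndarray:
        arr = np.array([self.counts.get(d, 0) for d in DINUCLEOTIDES], dtype=float)
        total = arr.sum()
        if total == 0:
            raise ValueError("degenerate profile: all dinucleotide counts are zero")
        return arr / total

    @property
    def nucleotide_probs(self) -> np.ndarray:
        arr = np.array(
            [self.nucleotide_counts.get(b, 0) for b in "ACGT"], dtype=float
        )
        total = arr.sum()
        if total == 0:
            raise ValueError("degenerate profile: all nucleotide counts are zero")
        return arr / total


@dataclass(frozen=True)
class PseudoMotifSet:
    """One iteration's pseudo-motifs, unique within the iteration."""

    motifs: tuple[str, ...]
    iteration_index: int


def dinucleotide_profile(motifs: Sequence[str]) -> DinucleotideProfile:
    """Count every overlapping adjacent base pair in every motif.

    Scanning both offset parities jointly covers all adjacent pairs, so a
    length-k motif contributes k - 1 dinucleotides.
    """
    counts: dict[str, int] = {}
    nuc_counts: dict[str, int] = {}
    for motif in motifs:
        motif = motif.upper()
        if len(motif) < 2:
            raise ValueError(f"motif {motif!r} shorter than a dinucleotide")
        for i in range(len(motif) - 1):
            counts[motif[i : i + 2]] = counts.get(motif[i : i + 2], 0) + 1
        for b in motif:
            nuc_counts[b] = nuc_counts.get(b, 0) + 1
    return DinucleotideProfile(counts, nuc_counts)


def sample_pseudo_motif(
    length: int, profile: DinucleotideProfile, rng: np.random.Generator
) -> str:
    """One pseudo-motif: floor(length/2) independent dinucleotide draws.

    Odd lengths get a single trailing nucleotide drawn from the profile's
    mononucleotide distribution.
    """
    if length < 2:
        raise ValueError("pseudo-motif length must be >= 2")
    n_pairs = length // 2
    pairs = rng.choice(len(DINUCLEOTIDES), size=n_pairs, p=profile.dinucleotide_probs)
    motif = "".join(DINUCLEOTIDES[i] for i in pairs)
    if length % 2:
        motif += "ACGT"[rng.choice(4, p=profile.nucleotide_probs)]
    return motif


def generate_pseudo_set(
    true_set: Sequence[str],
    rng: np.random.Generator,
    max_retries: int = 1000,
    profile: DinucleotideProfile | None = None,
    iteration_index: int = 0,
) -> PseudoMotifSet:
    """One pseudo-motif per true motif, same length, unique in the set.

    A draw colliding with a pseudo-motif already generated in this
    iteration is discarded and resampled (duplicates of the *real*
    motifs are allowed).  ``max_retries`` failed redraws for a single
    motif raise :class:`SaturationError` — the profile cannot support as
    many distinct motifs as the set requires.
    """
    if not true_set:
        raise ValueError("true motif set is empty")
    if profile is None:
        profile = dinucleotide_profile(true_set)
    seen: set[str] = set()
    out: list[str] = []
    for motif in true_set:
        for _ in range(max_retries):
            candidate = sample_pseudo_motif(len(motif), profile, rng)
            if candidate not in seen:
                seen.add(candidate)
                out.append(candidate)
                break
        else:
            raise SaturationError(
                f"could not draw a new distinct pseudo-motif of length "
                f"{len(motif)} after {max_retries} attempts"
            )
    return PseudoMotifSet(tuple(out), iteration_index)


def motif_null_distribution(
    true_set: Sequence[str],
    query,
    n_iterations: int = 10000,
    seed: int = 0,
    max_retries: int = 1000,
):
    """Null for the pooled density of ``query`` motifs in a motif set.

    Observed is the pooled coverage density of the query set (a codon
    set or any motif collection) over the true motifs; each simulant is
    the same density over one dinucleotide-matched pseudo-motif set.
    """
    from .enrichment import NullDistribution

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    true_set = list(true_set)
    profile = dinucleotide_profile(true_set)
    observed = pooled_density(true_set, query).density
    simulants = np.empty(n_iterations, dtype=float)
    for i, rng in enumerate(iteration_rngs(seed, n_iterations)):
        pseudo = generate_pseudo_set(
            true_set, rng, max_retries=max_retries, profile=profile, iteration_index=i
        )
        simulants[i] = pooled_density(pseudo.motifs, query).density
    return NullDistribution(observed, simulants)
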