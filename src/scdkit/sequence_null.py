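"""Sequence-level null models built on mononucleotide shuffles.

Every null preserves the base composition of its scope unit: a whole
transcript, an individual part of a masked sequence, or the pooled
nucleotides of an entire cohort (shuffled as one concatenation and
re-cut into the original lengths).  Randomness flows from one master
seed; each iteration draws from its own child stream so iterations are
order-independent.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """A uniform random permutation of the characters of ``seq``."""
    return _array_to_seq(rng.permutation(_seq_to_array(seq)))


def shuffle_parts(parts: Sequence[str], rng: np.random.Generator) -> list[str]:
    """Shuffle each part independently, preserving part count and lengths.

    Used for nulls of masked sequence: shuffling within each unmatched
    part keeps the part-length structure of the original fixed.
    """
    return [shuffle_sequence(p, rng) for p in parts]


def concat_shuffle_extract(
    seqs: Sequence[str], rng: np.random.Generator
) -> list[str]:
    """Shuffle the concatenation of all sequences and re-cut to lengths.

    Output sequence i has the length of input sequence i; the pooled
    character multiset is preserved exactly.  This is the length-matched
    cohort null used for pseudo-ORF threshold calibration.
    """
    if not seqs:
        raise ValueError("concat_shuffle_extract requires at least one sequence")
    pool = rng.permutation(_seq_to_array("".join(seqs)))
    out = []
    offset = 0
    for seq in seqs:
        out.append(_array_to_seq(pool[offset : offset + len(seq)]))
        offset += len(seq)
    return out


_SCOPES = ("whole-transcript", "per-exon", "per-part", "pooled-extraction")


def iteration_rngs(seed: int, n_iterations: int) -> list[np.random.Generator]:
    """Independent per-iteration generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_iterations)]


def sequence_null_distribution(
    seqs: Sequence[str],
    statistic: Callable[[list[str]], float],
    n_iterations: int = 1000,
    seed: int = 0,
    scope: str = "whole-transcript",
):
    """Observed statistic plus its distribution over shuffled sequence sets.

    ``scope`` selects the shuffle unit: ``whole-transcript``, ``per-exon``
    and ``per-part`` all shuffle each element of ``seqs`` independently
    (the caller decides what an element is); ``pooled-extraction`` uses
    :func:`concat_shuffle_extract`.
    """
    from .enrichment import NullDistribution

    if scope not in _SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {_SCOPES}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    seqs = list(seqs)
    observed = statistic(seqs)
    simulants = np.empty(n_iterations, dtype=float)
    for i, rng in enumerate(iteration_rngs(seed, n_iterations)):
        if scope == "pooled-extraction":
            shuffled = concat_shuffle_extract(seqs, rng)
        else:
            shuffled = shuffle_parts(seqs, rng)
        try:
            simulants[i] = statistic(shuffled)
        except Exception as exc:  # noqa: BLE001 - annotate iteration and re-raise
            raise RuntimeError(f"statistic failed at iteration {i}") from exc
    return NullDistribution(observed, simulants)


def per_gene_fe(
    seqs: Sequence[str],
    statistic: Callable[[list[str]], float],
    n_iterations: int = 1000,
    seed: int = 0,
):
    """Pairwise mode: each sequence against shuffles of that same sequence.

    Returns a list of :class:`~scdkit.enrichment.EnrichmentResult`, one
    per input sequence, each computed from ``n_iterations`` shuffles of
    that sequence only.  The fraction of genes with FE < 0 is the
    headline number of the pairwise analysis.
    """
    from .enrichment import EnrichmentResult

    results = []
    gene_seeds = np.random.SeedSequence(seed).generate_state(len(seqs))
    for seq, gene_seed in zip(seqs, gene_seeds):
        dist = sequence_null_distribution(
            [seq], statistic, n_iterations=n_iterations, seed=int(gene_seed)
        )
        results.append(EnrichmentResult.from_null(dist))
    return results
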