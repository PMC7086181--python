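"""Pseudo-ORF detection and ORF-length null models.

A pseudo-ORF (pORF) is an ATG followed by in-frame codons up to and
including the first in-frame stop codon, scanned on the sense strand in
all three frames.  Noncoding transcripts depleted in stop codons carry
longer pORFs than their shuffled selves, which matters for ORF-length
based annotation: the excess of real sequences over a length-matched
shuffle null, as a function of the length threshold, calibrates how long
a "safe" annotation threshold must be.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .density import STOP_CODONS, validate_sequence
from .sequence_null import iteration_rngs, shuffle_sequence


@dataclass(frozen=True)
class PORFRecord:
    """Longest pseudo-ORF of one transcript (absent if none completes)."""

    transcript_id: str
    longest_porf_nt: Optional[int]

    @property
    def has_porf(self) -> bool:
        return self.longest_porf_nt is not None


def _find_all(seq: str, pattern: str) -> list[int]:
    positions = []
    i = seq.find(pattern)
    while i != -1:
        positions.append(i)
        i = seq.find(pattern, i + 1)
    return positions


def longest_porf_length(seq: str) -> Optional[int]:
    """Length of the longest ATG-to-in-frame-stop span, or None.

    Lengths run from the first base of ATG through the last base of the
    stop codon inclusive, so the minimum is 6 (ATG directly followed by a
    stop) and every length is a multiple of 3.
    """
    seq = validate_sequence(seq)
    # stop codon start positions bucketed by frame, sorted, for bisection
    stop_starts: list[list[int]] = [[], [], []]
    for stop in STOP_CODONS:
        for pos in _find_all(seq, stop):
            stop_starts[pos % 3].append(pos)
    for frame in stop_starts:
        frame.sort()
    best: Optional[int] = None
    for atg in _find_all(seq, "ATG"):
        frame = stop_starts[atg % 3]
        j = bisect_left(frame, atg + 3)
        if j < len(frame):
            length = frame[j] + 3 - atg
            if best is None or length > best:
                best = length
    return best


def longest_porf(seq: str, transcript_id: str = "") -> PORFRecord:
    return PORFRecord(transcript_id, longest_porf_length(seq))


def upstream_of_first_atg(seq: str) -> Optional[str]:
    """The prefix strictly 5' of the most 5' ATG; None if empty or no ATG."""
    seq = validate_sequence(seq)
    i = seq.find("ATG")
    if i <= 0:
        return None
    return seq[:i]


def porf_null(seq: str, n_iterations: int = 1000, seed: int = 0):
    """Null distribution of the longest pORF under whole-sequence shuffles.

    Shuffles in which no pORF completes score 0 so every iteration
    contributes a simulant; the real sequence must itself have a pORF.
    """
    from .enrichment import NullDistribution

    observed = longest_porf_length(seq)
    if observed is None:
        raise ValueError("sequence has no pseudo-ORF; excluded from Z analysis")
    simulants = np.empty(n_iterations, dtype=float)
    for i, rng in enumerate(iteration_rngs(seed, n_iterations)):
        length = longest_porf_length(shuffle_sequence(seq, rng))
        simulants[i] = 0 if length is None else length
    return NullDistribution(float(observed), simulants)


@dataclass(frozen=True)
class ThresholdCurve:
    """Excess of real over null pORF counts across length thresholds."""

    thresholds: np.ndarray
    real_counts: np.ndarray
    null_mean_counts: np.ndarray
    excess_fraction: np.ndarray
    smoothed_excess: np.ndarray
    five_percent_threshold: Optional[float]


def _count_at_least(lengths: Iterable[Optional[int]], t: int) -> int:
    return sum(1 for x in lengths if x is not None and x >= t)


def threshold_excess(
    real_lengths: Sequence[Optional[int]],
    null_length_sets: Sequence[Sequence[Optional[int]]],
    thresholds: Sequence[int],
    smoothing_frac: float = 0.75,
) -> ThresholdCurve:
    """Excess proportion of real sequences beyond each length threshold.

    Per threshold t: (count of real pORFs >= t minus the mean count over
    null iterations) divided by the number of real sequences.  The
    5%-crossing threshold is read off a locally weighted regression of
    the excess on the threshold (linear interpolation between the
    bracketing thresholds); None if the smoothed curve never falls to 5%.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("thresholds must be nonempty")
    if not real_lengths:
        raise ValueError("need at least one real sequence")
    if not null_length_sets:
        raise ValueError("need at least one null iteration")
    n_real = len(real_lengths)
    real_counts = np.array(
        [_count_at_least(real_lengths, int(t)) for t in thresholds], dtype=float
    )
    null_counts = np.array(
        [
            [_count_at_least(null_set, int(t)) for t in thresholds]
            for null_set in null_length_sets
        ],
        dtype=float,
    )
    null_mean = null_counts.mean(axis=0)
    excess = (real_counts - null_mean) / n_real

    if thresholds.size >= 3:
        # it=0: plain locally weighted regression, no outlier reweighting
        # (robustness iterations would suppress genuine sharp declines)
        smoothed = lowess(
            excess, thresholds, frac=smoothing_frac, it=0, return_sorted=False
        )
    else:
        smoothed = excess.copy()

    five_pct: Optional[float] = None
    for i, value in enumerate(smoothed):
        if value <= 0.05:
            if i == 0:
                five_pct = float(thresholds[0])
            else:
                x0, x1 = thresholds[i - 1], thresholds[i]
                y0, y1 = smoothed[i - 1], smoothed[i]
                five_pct = float(x0 + (y0 - 0.05) * (x1 - x0) / (y0 - y1)) if y0 != y1 else float(x1)
            break
    return ThresholdCurve(
        thresholds=thresholds,
        real_counts=real_counts,
        null_mean_counts=null_mean,
        excess_fraction=excess,
        smoothed_excess=np.asarray(smoothed, dtype=float),
        five_percent_threshold=five_pct,
    )
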