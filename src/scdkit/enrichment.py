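"""Enrichment statistics and exon-region analysis.

Every null-model comparison in the package reduces to a
:class:`NullDistribution`: one observed statistic ``O`` and the statistic
recomputed on each of ``n`` null simulants.  From it come

* fold enrichment  FE = (O - E)/E  with E the simulant mean — negative
  values indicate depletion relative to the null, positive enrichment;
* the Z score  (O - mean)/sd  with the sample standard deviation
  (n - 1 denominator) of the simulants;
* the empirical p value  (m + 1)/(n + 1)  with m the number of simulants
  at or beyond O in the tested tail.

The module also hosts the exon-region partition (5' flank / core /
3' flank, each 67 nt, defined for exons longer than 207 nt) and the
region and exon-versus-intron comparisons built on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chisquare

from . import sequence_null
from .density import STOP_CODONS, find_hits, pooled_density, validate_sequence

Tail = Literal["lower", "upper"]


@dataclass(frozen=True)
class NullDistribution:
    """An observed statistic and its values under a null model."""

    observed: float
    simulants: np.ndarray

    def __post_init__(self) -> None:
        sims = np.asarray(self.simulants, dtype=float)
        if sims.ndim != 1 or sims.size < 1:
            raise ValueError("simulants must be a nonempty 1-d array")
        object.__setattr__(self, "simulants", sims)

    @property
    def n_iterations(self) -> int:
        return int(self.simulants.size)


def fold_enrichment(dist: NullDistribution) -> float:
    """(O - E)/E with E the simulant mean; requires E > 0."""
    expected = float(np.mean(dist.simulants))
    if expected <= 0:
        raise ValueError("fold enrichment undefined: simulant mean is not positive")
    return (dist.observed - expected) / expected


def z_score(dist: NullDistribution) -> float:
    """(O - mean)/sd with the sample (n-1) standard deviation."""
    if dist.n_iterations < 2:
        raise ValueError("z score requires at least 2 simulants")
    sd = float(np.std(dist.simulants, ddof=1))
    if sd == 0:
        raise ValueError("z score undefined: simulant standard deviation is zero")
    return (dist.observed - float(np.mean(dist.simulants))) / sd


def empirical_p(dist: NullDistribution, tail: Tail) -> tuple[float, int]:
    """Empirical p = (m + 1)/(n + 1); ties with O count toward m.

    ``lower`` counts simulants <= O (depletion test); ``upper`` counts
    simulants >= O (enrichment test).
    """
    if tail == "lower":
        m = int(np.sum(dist.simulants <= dist.observed))
    elif tail == "upper":
        m = int(np.sum(dist.simulants >= dist.observed))
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    return (m + 1) / (dist.n_iterations + 1), m


@dataclass(frozen=True)
class EnrichmentResult:
    """FE, Z and both-tail empirical p for one null comparison."""

    observed: float
    null_mean: float
    null_sd: float
    fe: float
    z: Optional[float]
    p_lower: float
    p_upper: float
    m_lower: int
    m_upper: int
    n_iterations: int

    @classmethod
    def from_null(cls, dist: NullDistribution) -> "EnrichmentResult":
        p_lo, m_lo = empirical_p(dist, "lower")
        p_up, m_up = empirical_p(dist, "upper")
        sd = float(np.std(dist.simulants, ddof=1)) if dist.n_iterations > 1 else 0.0
        try:
            z = z_score(dist)
        except ValueError:
            z = None
        return cls(
            observed=dist.observed,
            null_mean=float(np.mean(dist.simulants)),
            null_sd=sd,
            fe=fold_enrichment(dist),
            z=z,
            p_lower=p_lo,
            p_upper=p_up,
            m_lower=m_lo,
            m_upper=m_up,
            n_iterations=dist.n_iterations,
        )


# --- exon regions -----------------------------------------------------------

MIN_REGION_EXON_LENGTH = 207
REGION_WIDTH = 67


@dataclass(frozen=True)
class ExonRegions:
    """The three 67-nt windows of an exon longer than 207 nt.

    The 5' flank spans nucleotides 3-69 (1-based; the terminal 2 nt of
    each end are left out), the 3' flank mirrors it at the other
    terminus, and the core is the 67 nt centred on the exon midpoint
    (start biased 1 nt toward the 5' end when the centring is ambiguous).
    """

    flank5: str
    core: str
    flank3: str
    exon_length: int


def partition_exon(exon: str) -> ExonRegions:
    exon = validate_sequence(exon, context="exon")
    L = len(exon)
    if L <= MIN_REGION_EXON_LENGTH:
        raise ValueError(
            f"exon of length {L} too short for region analysis "
            f"(needs > {MIN_REGION_EXON_LENGTH} nt)"
        )
    core_start = (L - REGION_WIDTH) // 2
    return ExonRegions(
        flank5=exon[2:69],
        core=exon[core_start : core_start + REGION_WIDTH],
        flank3=exon[L - 69 : L - 2],
        exon_length=L,
    )


REGION_NAMES = ("flank5", "core", "flank3")


def region_analysis(
    transcripts: Iterable,
    ese_set: Sequence[str],
    n_iterations: int = 1000,
    seed: int = 0,
    codon_set: Sequence[str] = STOP_CODONS,
) -> pd.DataFrame:
    """Per-region ESE density and stop-codon enrichment statistics.

    Every exon longer than 207 nt contributes its three 67-nt regions.
    Per region the pooled ESE density and pooled codon-set density are
    computed, and the codon-set density is compared against
    mononucleotide shuffles of that region's sequences (each region
    simulated separately).  The returned frame has one row per region
    with observed/expected ratio (O/E), FE, Z and empirical p, plus a
    chi-square over region stop-covered counts against the null
    expectation as attribute ``attrs['chisquare']``.
    """
    regions: dict[str, list[str]] = {name: [] for name in REGION_NAMES}
    for tr in transcripts:
        for exon in tr.exons:
            if len(exon) > MIN_REGION_EXON_LENGTH:
                parts = partition_exon(exon)
                for name in REGION_NAMES:
                    regions[name].append(getattr(parts, name))
    if not regions["flank5"]:
        raise ValueError("no exon longer than 207 nt; region analysis impossible")

    rows = []
    dists = {}
    for i, name in enumerate(REGION_NAMES):
        seqs = regions[name]
        dist = sequence_null.sequence_null_distribution(
            seqs,
            lambda s: pooled_density(s, codon_set).density,
            n_iterations=n_iterations,
            seed=seed + i,
        )
        dists[name] = dist
        res = EnrichmentResult.from_null(dist)
        rows.append(
            {
                "region": name,
                "n_exons": len(seqs),
                "ese_density": pooled_density(seqs, ese_set).density,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "o_over_e": res.observed / res.null_mean if res.null_mean > 0 else np.nan,
                "fe": res.fe,
                "z": res.z,
                "p_lower": res.p_lower,
                "p_upper": res.p_upper,
                "n_iterations": res.n_iterations,
            }
        )
    frame = pd.DataFrame(rows)

    # chi-square on covered-position counts per region vs null expectation
    region_len = {n: sum(len(s) for s in regions[n]) for n in REGION_NAMES}
    obs_counts = [dists[n].observed * region_len[n] for n in REGION_NAMES]
    exp_counts = [float(np.mean(dists[n].simulants)) * region_len[n] for n in REGION_NAMES]
    exp_counts = np.asarray(exp_counts) * (sum(obs_counts) / sum(exp_counts))
    chi = chisquare(obs_counts, exp_counts)
    frame.attrs["chisquare"] = {"statistic": float(chi.statistic), "p": float(chi.pvalue)}
    return frame


@dataclass(frozen=True)
class PairedComparison:
    """Per-gene exon-vs-intron densities and the cohort-level test."""

    per_gene: pd.DataFrame = field(repr=False)
    n_genes: int
    n_exon_lower: int
    p_binomial: float
    n_excluded_intronless: int

    @property
    def fraction_exon_lower(self) -> float:
        return self.n_exon_lower / self.n_genes


def compare_exon_intron(
    transcripts: Iterable,
    codon_set: Sequence[str] = STOP_CODONS,
) -> PairedComparison:
    """Pairwise exonic-vs-intronic codon-set density per gene.

    A gene counts as a success only when its pooled exonic density is
    strictly below its pooled intronic density (ties fail).  Intronless
    transcripts are excluded and tallied.  The cohort p is a one-tailed
    exact binomial test at null success probability 0.5.
    """
    rows = []
    excluded = 0
    for tr in transcripts:
        if not tr.introns:
            excluded += 1
            continue
        exon_d = pooled_density(tr.exons, codon_set).density
        intron_d = pooled_density(tr.introns, codon_set).density
        rows.append(
            {
                "transcript_id": tr.transcript_id,
                "exon_density": exon_d,
                "intron_density": intron_d,
                "exon_lower": exon_d < intron_d,
            }
        )
    if not rows:
        raise ValueError("no transcript with introns; exon-intron comparison impossible")
    per_gene = pd.DataFrame(rows)
    n = len(per_gene)
    k = int(per_gene["exon_lower"].sum())
    p = binomtest(k, n, p=0.5, alternative="greater").pvalue
    return PairedComparison(per_gene, n, k, float(p), excluded)
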