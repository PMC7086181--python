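"""FE / Z / empirical-p formulas, exon regions, paired comparisons."""

import numpy as np
import pytest

from scdkit.density import STOP_CODONS
from scdkit.enrichment import (
    EnrichmentResult,
    NullDistribution,
    compare_exon_intron,
    empirical_p,
    fold_enrichment,
    partition_exon,
    region_analysis,
    z_score,
)
from scdkit.seqio import TranscriptModel


def _dist(observed, simulants):
    return NullDistribution(observed, np.asarray(simulants, dtype=float))


class TestFoldEnrichment:
    @pytest.mark.parametrize(
        "observed, simulants, expected",
        [
            (2.0, [2.0, 2.0], 0.0),        # O = E
            (0.0, [1.0, 3.0], -1.0),       # maximal depletion
            (1.5, [1.0, 1.0, 1.0], 0.5),
        ],
    )
    def test_closed_forms(self, observed, simulants, expected):
        assert fold_enrichment(_dist(observed, simulants)) == pytest.approx(expected)

    def test_zero_expectation_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            fold_enrichment(_dist(1.0, [0.0, 0.0]))


class TestZScore:
    def test_zero_at_mean(self):
        assert z_score(_dist(2.0, [1.0, 3.0])) == 0.0

    def test_sample_sd_convention(self):
        # simulants {1, 3}: mean 2, sample sd sqrt(2); O = 3 gives 1/sqrt(2)
        assert z_score(_dist(3.0, [1.0, 3.0])) == pytest.approx(1 / np.sqrt(2))

    def test_antisymmetry_about_mean(self):
        sims = [1.0, 2.0, 3.0, 6.0]
        mean = np.mean(sims)
        assert z_score(_dist(mean + 1.3, sims)) == pytest.approx(
            -z_score(_dist(mean - 1.3, sims))
        )

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="standard deviation"):
            z_score(_dist(1.0, [2.0, 2.0]))


class TestEmpiricalP:
    def test_most_extreme_observation(self):
        sims = np.arange(1, 1001, dtype=float)
        p, m = empirical_p(_dist(0.5, sims), "lower")
        assert m == 0
        assert p == pytest.approx(9.99e-4, rel=1e-3)

    def test_tails_complement(self):
        sims = [1.0, 2.0, 3.0, 4.0]
        dist = _dist(0.0, sims)  # below every simulant
        assert empirical_p(dist, "lower") == (1 / 5, 0)
        assert empirical_p(dist, "upper") == (1.0, 4)

    def test_ties_count_in_m(self):
        dist = _dist(2.0, [2.0, 2.0, 2.0])
        assert empirical_p(dist, "lower") == (1.0, 3)
        assert empirical_p(dist, "upper") == (1.0, 3)

    def test_bounds_and_m_overlap_invariant(self, rng):
        for _ in range(20):
            sims = rng.normal(size=50)
            dist = _dist(rng.normal(), sims)
            p_lo, m_lo = empirical_p(dist, "lower")
            p_up, m_up = empirical_p(dist, "upper")
            n = dist.n_iterations
            assert 1 / (n + 1) <= p_lo <= 1.0
            assert 1 / (n + 1) <= p_up <= 1.0
            assert m_lo + m_up >= n

    def test_fe_and_z_invariant_to_simulant_order(self, rng):
        sims = rng.normal(loc=5, size=40)
        shuffled = rng.permutation(sims)
        assert fold_enrichment(_dist(4.0, sims)) == fold_enrichment(_dist(4.0, shuffled))
        assert z_score(_dist(4.0, sims)) == z_score(_dist(4.0, shuffled))


class TestEnrichmentResult:
    def test_degenerate_simulants_yield_no_z(self):
        res = EnrichmentResult.from_null(_dist(1.0, [2.0, 2.0]))
        assert res.z is None
        assert res.fe == pytest.approx(-0.5)


class TestPartitionExon:
    def test_length_208_boundaries(self, rng):
        exon = "".join(rng.choice(list("ACGT"), 208))
        regions = partition_exon(exon)
        assert regions.flank5 == exon[2:69]
        assert regions.core == exon[70:137]
        assert regions.flank3 == exon[139:206]
        assert len(regions.flank5) == len(regions.core) == len(regions.flank3) == 67

    def test_reverse_complement_swaps_flanks(self, rng):
        from Bio.Seq import Seq

        exon = "".join(rng.choice(list("ACGT"), 301))
        fwd = partition_exon(exon)
        rev = partition_exon(str(Seq(exon).reverse_complement()))
        assert rev.flank5 == str(Seq(fwd.flank3).reverse_complement())
        assert rev.flank3 == str(Seq(fwd.flank5).reverse_complement())

    def test_regions_disjoint_and_away_from_termini(self, rng):
        for L in (208, 209, 250, 301, 500):
            exon = "".join(rng.choice(list("ACGT"), L))
            r = partition_exon(exon)
            core_start = (L - 67) // 2
            intervals = [(2, 69), (core_start, core_start + 67), (L - 69, L - 2)]
            for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
                assert b1 <= a2
            assert intervals[0][0] >= 2 and intervals[-1][1] <= L - 2

    def test_length_207_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            partition_exon("A" * 207)


class TestRegionAnalysis:
    def test_planted_flank_recovers_gradient(self, small_planted_cohort):
        transcripts, truth = small_planted_cohort
        frame = region_analysis(transcripts, truth.ese_set, n_iterations=60, seed=0)
        by_region = frame.set_index("region")
        # planting gradient flank5 > core > flank3 shows in ESE density ...
        assert (
            by_region.loc["flank5", "ese_density"]
            > by_region.loc["core", "ese_density"]
            > by_region.loc["flank3", "ese_density"]
        )
        # ... and in stop-codon depletion (stop-free motifs overwrite background)
        assert by_region.loc["flank5", "fe"] < by_region.loc["core", "fe"]
        assert "chisquare" in frame.attrs

    def test_no_qualifying_exons_rejected(self):
        transcripts = [TranscriptModel("t", ("ACGT" * 10,))]
        with pytest.raises(ValueError, match="region"):
            region_analysis(transcripts, ["GAAGAA"], n_iterations=5, seed=0)


class TestCompareExonIntron:
    def test_identical_sequences_tie_counts_as_failure(self):
        seq = "ACGTACGTAATT"
        transcripts = [TranscriptModel("t", (seq, seq), (seq,))]
        comp = compare_exon_intron(transcripts)
        assert comp.n_exon_lower == 0

    def test_stop_depleted_exons_detected(self):
        # exons free of stop codons, introns AT-rich with stops
        transcripts = [
            TranscriptModel(
                f"g{i}",
                ("GGCGGCGGCGGC", "CCGCCGCCGCCG"),
                ("TAATGATAGTAA",),
            )
            for i in range(10)
        ]
        comp = compare_exon_intron(transcripts)
        assert comp.fraction_exon_lower == 1.0
        assert comp.p_binomial < 0.01

    def test_single_gene_report_well_formed(self):
        transcripts = [TranscriptModel("g", ("GGCGGC", "CCGCCG"), ("TAATGA",))]
        comp = compare_exon_intron(transcripts)
        assert comp.n_genes == 1
        assert 0 < comp.p_binomial <= 1

    def test_intronless_excluded_and_counted(self):
        transcripts = [
            TranscriptModel("multi", ("GGCGGC", "CCGCCG"), ("TAATGA",)),
            TranscriptModel("single", ("ACGTACGT",)),
        ]
        comp = compare_exon_intron(transcripts)
        assert comp.n_genes == 1
        assert comp.n_excluded_intronless == 1

    def test_all_intronless_rejected(self):
        with pytest.raises(ValueError):
            compare_exon_intron([TranscriptModel("s", ("ACGT",))])
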