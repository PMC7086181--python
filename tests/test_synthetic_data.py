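"""Generator contracts: motif policies, plant guarantees, calibration."""

import json

import numpy as np
import pytest

from scdkit.density import motif_contains_stop, pooled_scd
from scdkit.enrichment import fold_enrichment
from scdkit.orf import longest_porf_length
from scdkit.sequence_null import sequence_null_distribution
from scdkit.seqio import read_transcripts
from scdkit.synthetic_data import (
    SaturationError,
    SyntheticConfig,
    generate_cohort,
    generate_motif_set,
    write_cohort,
)


class TestGenerateMotifSet:
    def test_forbid_policy_yields_stop_free_unique_hexamers(self):
        motifs = generate_motif_set(84, 6, "forbid", seed=1)
        assert len(motifs) == 84
        assert len(set(motifs)) == 84
        assert all(len(m) == 6 for m in motifs)
        assert not any(motif_contains_stop(m) for m in motifs)

    def test_force_policy_plants_a_stop_in_every_motif(self):
        motifs = generate_motif_set(30, 6, "force", seed=2)
        assert all(motif_contains_stop(m) for m in motifs)

    def test_fixed_seed_identical(self):
        assert generate_motif_set(20, 6, "forbid", seed=3) == generate_motif_set(
            20, 6, "forbid", seed=3
        )

    def test_gc_target_approached_for_large_sets(self):
        motifs = generate_motif_set(200, 6, "allow", gc=0.6, seed=4)
        joined = "".join(motifs)
        gc = sum(b in "GC" for b in joined) / len(joined)
        assert abs(gc - 0.6) < 0.05

    def test_unreachable_request_saturates(self):
        # only 4^2 = 16 distinct dimers exist
        with pytest.raises(SaturationError):
            generate_motif_set(17, 2, "allow", seed=5)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            generate_motif_set(5, 6, "sometimes", seed=0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"exon_length_range": (500, 250)},
            {"flank_planting_density": 1.5},
            {"planted_orf_length": 7},
            {"planted_orf_length": 3},
            {"gc_content": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cfg = SyntheticConfig(**kwargs)
            if "gc_content" in kwargs:  # validated at sequence generation
                generate_cohort(cfg)


class TestGenerateCohort:
    def test_planted_intervals_within_bounds_and_disjoint(self, small_planted_cohort):
        transcripts, truth = small_planted_cohort
        by_id = {t.transcript_id: t for t in transcripts}
        for gene, intervals in truth.planted_ese.items():
            per_exon: dict[int, list[tuple[int, int]]] = {}
            for exon_idx, start, end, motif in intervals:
                exon = by_id[gene].exons[exon_idx]
                assert 0 <= start < end <= len(exon)
                assert exon[start:end] == motif
                per_exon.setdefault(exon_idx, []).append((start, end))
            for spans in per_exon.values():
                spans.sort()
                for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
                    assert b1 <= a2

    def test_planted_orf_always_detected(self):
        config = SyntheticConfig(
            n_genes=15,
            exon_length_range=(400, 600),
            planted_orf_length=360,
            flank_planting_density=0.0,
            core_planting_density=0.0,
            flank3_planting_density=0.0,
            seed=5,
        )
        transcripts, truth = generate_cohort(config)
        assert len(truth.planted_orf) == 15
        for tr in transcripts:
            assert longest_porf_length(tr.spliced) >= 360

    def test_unplanted_scd_matches_iid_oracle(self):
        # Monte-Carlo oracle: pooled SCD of the cohort vs fresh i.i.d.
        # sequence of the same composition and total length
        config = SyntheticConfig(
            n_genes=40,
            flank_planting_density=0.0,
            core_planting_density=0.0,
            flank3_planting_density=0.0,
            seed=6,
        )
        transcripts, _ = generate_cohort(config)
        seqs = [t.spliced for t in transcripts]
        total = sum(len(s) for s in seqs)
        gc = config.gc_content
        gen = np.random.default_rng(99)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        oracle = [
            pooled_scd(["".join(gen.choice(list("ACGT"), 4000, p=probs))])
            for _ in range(60)
        ]
        mu, sd = np.mean(oracle), np.std(oracle, ddof=1)
        # cohort pooled SCD is one draw at much larger n; allow 3 sigma of
        # the small-oracle spread, which upper-bounds the cohort's own
        assert abs(pooled_scd(seqs) - mu) < 3 * sd

    def test_planting_monotonically_deepens_depletion(self):
        fes = []
        for theta in (0.0, 0.1, 0.2, 0.3):
            config = SyntheticConfig(
                n_genes=60,
                flank_planting_density=theta,
                core_planting_density=theta,
                flank3_planting_density=theta,
                seed=7,
            )
            transcripts, _ = generate_cohort(config)
            dist = sequence_null_distribution(
                [t.spliced for t in transcripts],
                pooled_scd,
                n_iterations=80,
                seed=8,
            )
            fes.append(fold_enrichment(dist))
        assert all(b < a for a, b in zip(fes, fes[1:]))

    def test_single_exon_cohorts_supported(self):
        config = SyntheticConfig(
            n_genes=5,
            exon_count_range=(1, 1),
            flank_planting_density=0.0,
            core_planting_density=0.0,
            flank3_planting_density=0.0,
            seed=9,
        )
        transcripts, _ = generate_cohort(config)
        assert all(len(t.exons) == 1 and not t.introns for t in transcripts)

    def test_fixed_seed_reproducible(self):
        config = SyntheticConfig(n_genes=5, seed=10)
        a, _ = generate_cohort(config)
        b, _ = generate_cohort(config)
        assert a == b


class TestWriteCohort:
    def test_roundtrip_and_ground_truth_validate(self, tmp_path, small_planted_cohort):
        transcripts, truth = small_planted_cohort
        paths = write_cohort(transcripts, truth, tmp_path / "cohort")
        models = read_transcripts(paths["pre_mrna_fasta"], paths["exon_bed"])
        assert models == list(transcripts)
        payload = json.loads(paths["ground_truth"].read_text())
        by_id = {t.transcript_id: t for t in transcripts}
        for gene, intervals in payload["planted_ese"].items():
            for exon_idx, start, end, motif in intervals:
                assert by_id[gene].exons[exon_idx][start:end] == motif

    def test_rerun_same_seed_byte_identical(self, tmp_path):
        config = SyntheticConfig(n_genes=4, seed=11)
        out = []
        for name in ("a", "b"):
            transcripts, truth = generate_cohort(config)
            paths = write_cohort(transcripts, truth, tmp_path / name)
            out.append(paths["pre_mrna_fasta"].read_bytes())
        assert out[0] == out[1]
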