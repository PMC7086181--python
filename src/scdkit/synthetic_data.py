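"""Synthetic motif sets and multi-exon transcript cohorts.

The generator emulates the statistical structure the analysis assumes
about spliced noncoding transcripts: background sequence drawn i.i.d.
from a GC-parameterised composition, splice-enhancer motifs planted
preferentially in the 5' flanks of exons (overwriting background, so
declared lengths never shift), and optionally a stop-free open reading
frame planted in one exon.  Every insertion is recorded in a ground
truth object so planted-signal recovery can be asserted exactly.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .density import STOP_CODONS, motif_contains_stop
from .enrichment import MIN_REGION_EXON_LENGTH, REGION_WIDTH
from .seqio import TranscriptModel, write_motif_list, write_transcripts


class SaturationError(RuntimeError):
    """Raised when a motif-set request cannot be satisfied."""


def _base_probs(gc: float) -> np.ndarray:
    if not 0 < gc < 1:
        raise ValueError("gc_content must be in (0, 1)")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=length, p=_base_probs(gc))
    return "".join("ACGT"[i] for i in idx)


def generate_motif_set(
    n: int,
    length: int = 6,
    stop_codon_policy: str = "forbid",
    gc: float = 0.5,
    seed: int = 0,
) -> list[str]:
    """``n`` unique k-mers sampled from a GC-parameterised composition.

    ``stop_codon_policy`` controls stop-triplet content: ``forbid``
    rejects any motif containing TAA/TAG/TGA (emulating enhancer motifs
    constrained by coding sequence), ``force`` requires at least one,
    ``allow`` applies no constraint.
    """
    if stop_codon_policy not in ("forbid", "allow", "force"):
        raise ValueError(f"unknown stop_codon_policy {stop_codon_policy!r}")
    rng = np.random.default_rng(seed)
    motifs: list[str] = []
    seen: set[str] = set()
    max_attempts = max(10000, n * 1000)
    for _ in range(max_attempts):
        if len(motifs) == n:
            break
        motif = _random_seq(length, gc, rng)
        if motif in seen:
            continue
        has_stop = motif_contains_stop(motif)
        if stop_codon_policy == "forbid" and has_stop:
            continue
        if stop_codon_policy == "force" and not has_stop:
            continue
        seen.add(motif)
        motifs.append(motif)
    if len(motifs) < n:
        raise SaturationError(
            f"could only generate {len(motifs)}/{n} distinct motifs of "
            f"length {length} under policy {stop_codon_policy!r}"
        )
    return motifs


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    Defaults emulate a cohort of spliced noncoding transcripts: a few
    hundred genes of 2-4 exons, exon lengths long enough for the
    three-region analysis, overall GC content of 0.46 (typical for
    noncoding transcripts), and an 84-hexamer stop-free enhancer set
    planted most densely in 5' flanks, less in cores and least in 3'
    flanks — the spatial gradient the analysis is designed to detect.
    """

    n_genes: int = 200
    exon_count_range: tuple[int, int] = (2, 4)
    exon_length_range: tuple[int, int] = (250, 500)
    intron_length_range: tuple[int, int] = (150, 800)
    gc_content: float = 0.46
    ese_set: Optional[tuple[str, ...]] = None
    ese_set_size: int = 84
    ese_length: int = 6
    flank_planting_density: float = 0.30
    core_planting_density: float = 0.10
    flank3_planting_density: float = 0.05
    planted_orf_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("exon_count_range", "exon_length_range", "intron_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        for name in (
            "flank_planting_density",
            "core_planting_density",
            "flank3_planting_density",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.planted_orf_length is not None and (
            self.planted_orf_length < 6 or self.planted_orf_length % 3
        ):
            raise ValueError("planted_orf_length must be a multiple of 3, >= 6")

    def resolve_ese_set(self) -> list[str]:
        if self.ese_set is not None:
            return list(self.ese_set)
        return generate_motif_set(
            self.ese_set_size, self.ese_length, "forbid", gc=0.5, seed=self.seed
        )


@dataclass
class GroundTruth:
    """Every planted interval, per gene, plus the generating config."""

    config: SyntheticConfig
    ese_set: list[str]
    planted_ese: dict[str, list[tuple[int, int, int, str]]] = field(default_factory=dict)
    planted_orf: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _plant_region(
    exon: np.ndarray,
    blocked: np.ndarray,
    region: tuple[int, int],
    target_density: float,
    ese_set: Sequence[str],
    rng: np.random.Generator,
    records: list[tuple[int, int, str]],
) -> None:
    """Overwrite non-overlapping motifs inside ``region`` until coverage.

    Placement is by rejection sampling of uniform start positions; gives
    up once the target or an attempt budget is reached (random
    sequential packing saturates well above the densities used here).
    """
    a, b = region
    region_len = b - a
    target = target_density * region_len
    covered = 0
    attempts = 0
    max_attempts = 50 * region_len
    while covered < target and attempts < max_attempts:
        attempts += 1
        motif = ese_set[rng.integers(len(ese_set))]
        k = len(motif)
        if b - k < a:
            break
        start = int(rng.integers(a, b - k + 1))
        if blocked[start : start + k].any():
            continue
        exon[start : start + k] = np.frombuffer(motif.encode(), dtype=np.uint8)
        blocked[start : start + k] = True
        covered += k
        records.append((start, start + k, motif))


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Draw a cohort of transcript models under the configured conditions.

    Exons longer than 207 nt receive planted motifs in their 5' flank,
    core and 3' flank regions at the configured target coverages; other
    exons are left as background.  When ``planted_orf_length`` is set an
    ATG + stop-free codons + stop span is written into one sufficiently
    long exon per gene, before motif planting, and motifs never
    overwrite it.
    """
    rng = np.random.default_rng(config.seed)
    ese_set = config.resolve_ese_set()
    truth = GroundTruth(config=config, ese_set=list(ese_set))
    non_stop_codons = [
        "".join(t)
        for t in itertools.product("ACGT", repeat=3)
        if "".join(t) not in STOP_CODONS
    ]
    transcripts: list[TranscriptModel] = []
    for g in range(config.n_genes):
        gene_id = f"synth{g:05d}"
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        exon_lengths = [
            int(rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1))
            for _ in range(n_exons)
        ]
        exons = [
            np.frombuffer(
                _random_seq(L, config.gc_content, rng).encode(), dtype=np.uint8
            ).copy()
            for L in exon_lengths
        ]
        blocked = [np.zeros(L, dtype=bool) for L in exon_lengths]

        if config.planted_orf_length is not None:
            orf_len = config.planted_orf_length
            candidates = [i for i, L in enumerate(exon_lengths) if L >= orf_len]
            if not candidates:
                truth.warnings.append(f"{gene_id}: no exon long enough for {orf_len}-nt ORF")
            else:
                ei = candidates[int(rng.integers(len(candidates)))]
                start = int(rng.integers(0, exon_lengths[ei] - orf_len + 1))
                body_idx = rng.integers(len(non_stop_codons), size=orf_len // 3 - 2)
                orf = (
                    "ATG"
                    + "".join(non_stop_codons[i] for i in body_idx)
                    + STOP_CODONS[int(rng.integers(3))]
                )
                exons[ei][start : start + orf_len] = np.frombuffer(
                    orf.encode(), dtype=np.uint8
                )
                blocked[ei][start : start + orf_len] = True
                truth.planted_orf[gene_id] = (ei, start, start + orf_len)

        gene_eses: list[tuple[int, int, int, str]] = []
        for ei, L in enumerate(exon_lengths):
            if L <= MIN_REGION_EXON_LENGTH:
                continue
            core_start = (L - REGION_WIDTH) // 2
            for region, density in (
                ((2, 69), config.flank_planting_density),
                ((core_start, core_start + REGION_WIDTH), config.core_planting_density),
                ((L - 69, L - 2), config.flank3_planting_density),
            ):
                if density <= 0:
                    continue
                placed: list[tuple[int, int, str]] = []
                _plant_region(exons[ei], blocked[ei], region, density, ese_set, rng, placed)
                gene_eses.extend((ei, s, e, m) for s, e, m in placed)
        if gene_eses:
            truth.planted_ese[gene_id] = gene_eses

        introns = tuple(
            _random_seq(
                int(rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1)),
                config.gc_content,
                rng,
            )
            for _ in range(n_exons - 1)
        )
        transcripts.append(
            TranscriptModel(
                gene_id,
                tuple(e.tobytes().decode() for e in exons),
                introns,
            )
        )
    return transcripts, truth


def write_cohort(
    transcripts: Sequence[TranscriptModel],
    ground_truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA (spliced + pre-mRNA), exon BED, motif list and JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pre_mrna_fasta": out / "pre_mrna.fa",
        "spliced_fasta": out / "spliced.fa",
        "exon_bed": out / "exons.bed",
        "motifs": out / "ese_motifs.txt",
        "ground_truth": out / "ground_truth.json",
    }
    write_transcripts(transcripts, paths["pre_mrna_fasta"], paths["exon_bed"])
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        [SeqRecord(Seq(tr.spliced), id=tr.transcript_id, description="") for tr in transcripts],
        str(paths["spliced_fasta"]),
        "fasta",
    )
    write_motif_list(ground_truth.ese_set, paths["motifs"])
    payload = {
        "config": dataclasses.asdict(ground_truth.config),
        "ese_set": ground_truth.ese_set,
        "planted_ese": ground_truth.planted_ese,
        "planted_orf": ground_truth.planted_orf,
        "warnings": ground_truth.warnings,
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=1))
    return paths
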