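"""Reading and writing motif lists, transcript models and family groupings.

Transcript models are the unit every density analysis runs over: the
ordered exon sequences of one gene plus the introns between them, stored
sense-strand.  Coordinates follow the BED convention (0-based,
half-open) throughout; minus-strand records are reverse-complemented at
ingest so downstream code never sees strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .density import validate_sequence


@dataclass(frozen=True)
class TranscriptModel:
    """Ordered exons and introns of one gene, sense-strand."""

    transcript_id: str
    exons: tuple[str, ...]
    introns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        if self.introns and len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"{self.transcript_id}: {len(self.introns)} introns do not fit "
                f"{len(self.exons)} exons (need exon count - 1)"
            )

    @property
    def is_multiexon(self) -> bool:
        return len(self.exons) >= 2

    @property
    def spliced(self) -> str:
        """The mature transcript: exons concatenated in order."""
        return "".join(self.exons)

    @property
    def pre_mrna(self) -> str:
        """Exons and introns interleaved in genomic order."""
        parts = [self.exons[0]]
        for intron, exon in zip(self.introns, self.exons[1:]):
            parts.append(intron)
            parts.append(exon)
        return "".join(parts)


def read_motif_list(path: str | Path) -> list[str]:
    """One motif per line; '#' comment lines ignored; duplicates collapse.

    Motifs are uppercased and returned in first-seen order.  A non-ACGT
    character is rejected with its line number; a file yielding no
    motifs is an error.
    """
    motifs: list[str] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                motif = validate_sequence(line, context="motif")
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
            if motif not in seen:
                seen.add(motif)
                motifs.append(motif)
    if not motifs:
        raise ValueError(f"{path}: empty motif set")
    return motifs


def write_motif_list(motifs: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{m}\n" for m in motifs))


def _read_bed(path: str | Path) -> dict[str, dict]:
    """BED (>=3 columns) grouped by record id, intervals sorted."""
    records: dict[str, dict] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 else "+"
            if start >= end:
                raise ValueError(f"{path}, line {lineno}: empty interval {start}-{end}")
            rec = records.setdefault(chrom, {"intervals": [], "strand": strand})
            if rec["strand"] != strand:
                raise ValueError(f"{path}: inconsistent strand for record {chrom}")
            rec["intervals"].append((start, end))
    for rec in records.values():
        rec["intervals"].sort()
    return records


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_transcripts(
    fasta: str | Path,
    exon_bed: str | Path | None = None,
    skip_invalid: bool = True,
) -> list[TranscriptModel]:
    """Assemble transcript models from FASTA records and exon intervals.

    Without a BED file every record becomes a single-exon model.  With
    one, exons are the BED intervals on each record (ascending, strictly
    non-overlapping, within bounds) and introns the gaps between them.
    Minus-strand records are reverse-complemented so the returned models
    are sense-strand.  Records containing noncanonical nucleotides are
    dropped with a warning by default, or rejected if ``skip_invalid``
    is False.
    """
    bed = _read_bed(exon_bed) if exon_bed is not None else {}
    models: list[TranscriptModel] = []
    seen_ids: set[str] = set()
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in seen_ids:
            raise ValueError(f"{fasta}: duplicate FASTA id {record.id!r}")
        seen_ids.add(record.id)
        try:
            seq = validate_sequence(str(record.seq), context=f"record {record.id!r}")
        except ValueError as exc:
            if skip_invalid:
                warnings.warn(f"skipping {record.id}: {exc}", stacklevel=2)
                continue
            raise
        entry = bed.get(record.id)
        if entry is None:
            models.append(TranscriptModel(record.id, (seq,)))
            continue
        exons: list[str] = []
        introns: list[str] = []
        prev_end: Optional[int] = None
        for start, end in entry["intervals"]:
            if end > len(seq):
                raise ValueError(
                    f"{record.id}: exon interval [{start},{end}) exceeds "
                    f"sequence length {len(seq)}"
                )
            if prev_end is not None:
                if start < prev_end:
                    raise ValueError(
                        f"{record.id}: overlapping exon intervals at {start}"
                    )
                introns.append(seq[prev_end:start])
            exons.append(seq[start:end])
            prev_end = end
        if entry["strand"] == "-":
            exons = [_revcomp(e) for e in reversed(exons)]
            introns = [_revcomp(i) for i in reversed(introns)]
        models.append(TranscriptModel(record.id, tuple(exons), tuple(introns)))
    return models


def write_transcripts(
    transcripts: Iterable[TranscriptModel],
    fasta: str | Path,
    exon_bed: str | Path | None = None,
) -> None:
    """Write pre-mRNA FASTA plus BED6 exon intervals (plus strand).

    Reading the pair back with :func:`read_transcripts` reproduces the
    models exactly.
    """
    records = []
    bed_lines = []
    for tr in transcripts:
        records.append(SeqRecord(Seq(tr.pre_mrna), id=tr.transcript_id, description=""))
        offset = 0
        for i, exon in enumerate(tr.exons):
            bed_lines.append(
                f"{tr.transcript_id}\t{offset}\t{offset + len(exon)}\t"
                f"exon{i + 1}\t0\t+\n"
            )
            offset += len(exon)
            if i < len(tr.introns):
                offset += len(tr.introns[i])
    SeqIO.write(records, str(fasta), "fasta")
    if exon_bed is not None:
        Path(exon_bed).write_text("".join(bed_lines))


@dataclass(frozen=True)
class FamilyGrouping:
    """A partition of transcript ids into paralogous families.

    Families are the connected components of the undirected similarity
    hit graph; ids with no hits form singleton families.  When one gene
    per family is needed, either a seeded random member or the
    per-statistic median across members represents the family.
    """

    families: tuple[tuple[str, ...], ...]
    representatives: tuple[str, ...] = field(default=())

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_of(self, transcript_id: str) -> tuple[str, ...]:
        for fam in self.families:
            if transcript_id in fam:
                return fam
        raise KeyError(transcript_id)

    def median_aggregate(self, values: dict[str, float]) -> dict[tuple[str, ...], float]:
        """Per-family median of a per-transcript statistic."""
        return {
            fam: float(np.median([values[tid] for tid in fam])) for fam in self.families
        }


def read_hit_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of pairwise similarity hits (no header)."""
    pairs = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}, line {lineno}: need two columns")
            pairs.append((fields[0], fields[1]))
    return pairs


def group_families(
    ids: Sequence[str],
    hits: Iterable[tuple[str, str]],
    seed: int = 0,
) -> FamilyGrouping:
    """Cluster ids into families by single-linkage over similarity hits.

    The result is invariant to hit order and pair orientation.  One
    random member per family, drawn with ``seed``, is stored as that
    family's representative.
    """
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    known = set(ids)
    for a, b in hits:
        for node in (a, b):
            if node not in known:
                raise ValueError(f"hit references unknown id {node!r}")
        graph.add_edge(a, b)
    families = tuple(
        sorted(tuple(sorted(component)) for component in nx.connected_components(graph))
    )
    rng = np.random.default_rng(seed)
    representatives = tuple(fam[rng.integers(len(fam))] for fam in families)
    return FamilyGrouping(families, representatives)
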