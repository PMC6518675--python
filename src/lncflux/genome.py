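"""Core genomic types: stranded, exon-structured transcripts and annotation sets.

Coordinates are 0-based half-open internally; GTF I/O converts to/from the
1-based closed convention of the format. Exons are kept sorted and
non-overlapping; the intron chain is derived, never stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import gffutils.feature
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lncflux")

Interval = tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome.

    ``exons`` are 0-based half-open ``(start, end)`` intervals, sorted and
    non-overlapping. ``sequence`` is the spliced transcript sequence (5'→3'
    in transcript orientation) when available.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[Interval, ...]
    sequence: str | None = None
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has zero exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if start >= end:
                raise ValueError(
                    f"empty or inverted exon ({start}, {end}) in {self.transcript_id}"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(f"overlapping/unsorted exons in {self.transcript_id}")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        """Summed exon length in bp (the conventional lncRNA length)."""
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def overlaps_exonic(self, other: "TranscriptModel") -> bool:
        """True if any exon of self intersects any exon of other."""
        if self.chromosome != other.chromosome:
            return False
        if self.end <= other.start or other.end <= self.start:
            return False
        for s1, e1 in self.exons:
            for s2, e2 in other.exons:
                if s1 < e2 and s2 < e1:
                    return True
        return False

    def with_sequence(self, sequence: str) -> "TranscriptModel":
        if len(sequence) != self.spliced_length:
            raise ValueError(
                f"sequence length {len(sequence)} != spliced length "
                f"{self.spliced_length} for {self.transcript_id}"
            )
        return replace(self, sequence=sequence)


@dataclass(frozen=True)
class GeneModel:
    """The genomic span of one gene (union of its transcripts)."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    def overlaps_span(self, start: int, end: int) -> bool:
        return start < self.end and self.start < end


@dataclass
class AnnotationSet:
    """A collection of transcripts with per-chromosome and per-gene indexes."""

    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_chrom: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            self._by_chrom.setdefault(t.chromosome, []).append(t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts)

    def on_chromosome(self, chromosome: str) -> list[TranscriptModel]:
        return self._by_chrom.get(chromosome, [])

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def genes(self, biotype: str | None = None) -> list[GeneModel]:
        """Gene spans, optionally restricted to one biotype.

        A gene's strand is taken from its transcripts; mixed-strand genes
        raise, as the simulator never emits them and real annotations
        should not either.
        """
        grouped: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            if biotype is not None and t.biotype != biotype:
                continue
            grouped.setdefault(t.gene_id, []).append(t)
        out = []
        for gene_id in sorted(grouped):
            ts = grouped[gene_id]
            strands = {t.strand for t in ts}
            if len(strands) > 1:
                raise ValueError(f"gene {gene_id} has transcripts on both strands")
            chroms = {t.chromosome for t in ts}
            if len(chroms) > 1:
                raise ValueError(f"gene {gene_id} spans multiple chromosomes")
            out.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=ts[0].chromosome,
                    strand=strands.pop(),
                    start=min(t.start for t in ts),
                    end=max(t.end for t in ts),
                )
            )
        return out


# ---------------------------------------------------------------------------
# GTF I/O (1-based closed on disk <-> 0-based half-open in memory)
# ---------------------------------------------------------------------------

_GTF_SOURCE = "lncflux"


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write one ``exon`` feature line per exon, sorted for determinism."""
    ordered = sorted(transcripts, key=lambda t: (t.chromosome, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in ordered:
            for start, end in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                if t.biotype:
                    attrs += f' biotype "{t.biotype}";'
                fh.write(
                    f"{t.chromosome}\t{_GTF_SOURCE}\texon\t{start + 1}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read an exon-level GTF into an AnnotationSet.

    Only ``exon`` features are used; ``gene_id``/``transcript_id`` attributes
    are required, ``biotype`` (or ``gene_biotype``) is optional.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # pragma: no cover - malformed input
                raise ValueError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise ValueError(
                    f"{path}: line {lineno} lacks gene_id/transcript_id"
                ) from exc
            biotype = ""
            for key in ("biotype", "gene_biotype", "transcript_biotype"):
                if key in feat.attributes:
                    biotype = feat.attributes[key][0]
                    break
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
            meta[tid] = (gid, feat.seqid, feat.strand, biotype)
    transcripts = []
    for tid in sorted(exons):
        gid, chrom, strand, biotype = meta[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chromosome=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tid])),
                biotype=biotype,
            )
        )
    return AnnotationSet(transcripts)


def write_transcript_fasta(
    transcripts: Iterable[TranscriptModel], path: str | Path
) -> None:
    """Write spliced transcript sequences keyed by transcript_id."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in sorted(transcripts, key=lambda t: t.transcript_id)
        if t.sequence is not None
    ]
    SeqIO.write(records, str(path), "fasta")


def attach_sequences(annotation: AnnotationSet, fasta_path: str | Path) -> AnnotationSet:
    """Return a new AnnotationSet with sequences from a transcript FASTA."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    for t in annotation:
        if t.transcript_id in seqs:
            out.append(t.with_sequence(seqs[t.transcript_id]))
        else:
            out.append(t)
    return AnnotationSet(out)
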