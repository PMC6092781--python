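"""Genome and gene-model handling: inner exons and their splice acceptors.

Splicing removes introns whose 3' end carries a nearly invariant ...AG
dinucleotide (the splice acceptor).  Disrupting the terminal guanosine of
that dinucleotide prevents the spliceosome from recognising the downstream
exon, so the exon is skipped.  Only *inner* exons (neither first nor last in
their transcript) are candidates: skipping a terminal exon truncates the
transcript instead.

Coordinates are 0-based half-open internally; GTF I/O follows the GTF
standard (1-based inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import gffutils
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: protein-coding biotype attribute keys recognised in GTF, in priority order
_BIOTYPE_KEYS = ("transcript_type", "transcript_biotype", "gene_type", "gene_biotype", "biotype")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    """Uppercase, map U->T and any other ambiguity code to N."""
    seq = seq.upper().replace("U", "T")
    return "".join(c if c in "ACGTN" else "N" for c in seq)


@dataclass
class Genome:
    """In-memory genome: contig name -> normalised nucleotide string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {name!r} contains non-normalised bases {bad}")

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the given strand (0-based half-open).

        Raises ``IndexError`` when the interval extends past the contig.
        """
        seq = self.sequences[contig]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"{contig}:[{start},{end}) outside contig of length {len(seq)}")
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub

    def reverse_complemented(self) -> "Genome":
        """A new genome with every contig reverse-complemented (for strand tests)."""
        return Genome({name: revcomp(seq) for name, seq in self.sequences.items()})


@dataclass
class TranscriptModel:
    """One transcript: exons ordered 5'->3' in transcript orientation.

    ``exons`` hold 0-based half-open genomic intervals; on the minus strand
    the list is ordered by decreasing genomic coordinate.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        starts = [e[0] for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"exons of {self.transcript_id} not ordered 5'->3'")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class ExonRef:
    """Reference to one exon of one transcript."""

    transcript_id: str
    exon_index: int  # 0-based within transcript (5'->3')
    contig: str
    start: int
    end: int
    strand: str
    n_exons: int
    gene_id: str = ""

    @property
    def is_inner(self) -> bool:
        return 0 < self.exon_index < self.n_exons - 1


@dataclass(frozen=True)
class AcceptorSite:
    """The conserved intronic G terminating the intron 5' of an inner exon.

    ``position`` is the 0-based genomic coordinate of the G; on the minus
    strand the G is the complement of the reference base at that position.
    ``dinucleotide`` is the last two intronic bases read on the transcript
    strand (canonically "AG"); ``canonical`` is False when it is not AG.
    """

    contig: str
    position: int
    strand: str
    exon: ExonRef
    dinucleotide: str
    canonical: bool


def load_genome(path) -> Genome:
    """Read a (multi-)FASTA into a :class:`Genome`.

    Sequences are uppercased, U mapped to T and other ambiguity codes to N.
    Duplicate contig names or an empty file are hard errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        sequences[rec.id] = _normalize(str(rec.seq))
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(sequences)


def _transcript_biotype(attrs) -> str | None:
    for key in _BIOTYPE_KEYS:
        if key in attrs:
            return attrs[key][0]
    return None


def load_annotation(path, coding_only: bool = False) -> list[TranscriptModel]:
    """Parse a GTF into transcript models.

    GTF exon features (1-based inclusive) are converted to 0-based half-open
    intervals and ordered 5'->3' on the transcript strand.  With
    ``coding_only`` transcripts whose biotype is not ``protein_coding`` are
    dropped.  Exon features lacking a transcript_id are skipped with a
    warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes:
            logger.warning("exon at %s:%d-%d has no transcript_id; skipped", feat.seqid, feat.start, feat.end)
            continue
        tid = feat.attributes["transcript_id"][0]
        entry = by_tx.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [""])[0],
                "contig": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "biotype": _transcript_biotype(feat.attributes),
            },
        )
        # GTF is 1-based inclusive: [start-1, end) half-open
        entry["exons"].append((feat.start - 1, feat.end))

    transcripts: list[TranscriptModel] = []
    for tid, entry in by_tx.items():
        coding = entry["biotype"] in (None, "protein_coding")
        if coding_only and entry["biotype"] != "protein_coding":
            continue
        exons = sorted(entry["exons"], reverse=(entry["strand"] == "-"))
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                contig=entry["contig"],
                strand=entry["strand"],
                exons=exons,
                coding=coding,
            )
        )
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write exon features back to GTF (1-based inclusive, genomic order)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            biotype = "protein_coding" if tx.coding else "misc_RNA"
            for start, end in sorted(tx.exons):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'transcript_type "{biotype}";'
                )
                fh.write(
                    f"{tx.contig}\texonskip\texon\t{start + 1}\t{end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def exon_refs(transcript: TranscriptModel) -> list[ExonRef]:
    """All exons of a transcript as :class:`ExonRef` objects."""
    return [
        ExonRef(
            transcript_id=transcript.transcript_id,
            exon_index=i,
            contig=transcript.contig,
            start=s,
            end=e,
            strand=transcript.strand,
            n_exons=transcript.n_exons,
            gene_id=transcript.gene_id,
        )
        for i, (s, e) in enumerate(transcript.exons)
    ]


def inner_exons(transcripts: Iterable[TranscriptModel], dedupe: bool = False) -> list[ExonRef]:
    """Exons with 0 < index < n_exons - 1 across all transcripts.

    With ``dedupe``, exons sharing (contig, interval, strand) across
    transcripts are reported once (first occurrence kept); each surviving
    ExonRef still names the transcript it came from.
    """
    out: list[ExonRef] = []
    seen: set[tuple] = set()
    for tx in transcripts:
        for ref in exon_refs(tx):
            if not ref.is_inner:
                continue
            key = (ref.contig, ref.start, ref.end, ref.strand)
            if dedupe:
                if key in seen:
                    continue
                seen.add(key)
            out.append(ref)
    return out


def acceptor_of(exon: ExonRef, genome: Genome) -> AcceptorSite:
    """Locate the splice-acceptor G of an inner exon.

    On the plus strand the G sits at ``exon.start - 1``; on the minus strand
    at ``exon.end`` (read as the complement).  The two terminal intronic
    bases are recorded on the transcript strand and flagged when not "AG".
    """
    if not exon.is_inner:
        raise ValueError(f"exon {exon.transcript_id}:{exon.exon_index} is not an inner exon")
    contig_len = len(genome.sequences[exon.contig])
    if exon.strand == "+":
        if exon.start < 2:
            raise ValueError(f"no intronic flank 5' of exon at {exon.contig}:{exon.start}")
        position = exon.start - 1
        dinuc = genome.fetch(exon.contig, exon.start - 2, exon.start, "+")
    else:
        if exon.end > contig_len - 2:
            raise ValueError(f"no intronic flank 5' of exon at {exon.contig}:{exon.end} (-)")
        position = exon.end
        dinuc = genome.fetch(exon.contig, exon.end, exon.end + 2, "-")
    site = AcceptorSite(
        contig=exon.contig,
        position=position,
        strand=exon.strand,
        exon=exon,
        dinucleotide=dinuc,
        canonical=dinuc == "AG",
    )
    if not site.canonical:
        logger.warning(
            "non-canonical acceptor %s at %s:%d (%s) for %s exon %d",
            dinuc, exon.contig, position, exon.strand, exon.transcript_id, exon.exon_index,
        )
    return site


def acceptors_to_bed(sites: Iterable[AcceptorSite], path) -> None:
    """BED6 export of acceptor G positions (0-based half-open)."""
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.exon.transcript_id}:{s.exon.exon_index}"
            fh.write(f"{s.contig}\t{s.position}\t{s.position + 1}\t{name}\t0\t{s.strand}\n")
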