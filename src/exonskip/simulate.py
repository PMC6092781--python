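"""Deterministic synthetic fixtures: toy genomes, pileups, junction reads.

Everything downstream of guide design is testable without external data by
generating small genomes with multi-exon transcripts whose introns end in
AG, PAMs planted so that the acceptor's antisense C lands at a requested
protospacer position, off-target sites planted at controlled mismatch
counts, and sequencing-style outputs (per-position pileups, paired junction
reads) simulated at known edit rates, skip fractions and error rates.

A single integer seed drives every artifact; each artifact kind uses its
own fixed substream so adding one fixture never reshuffles the others.
A ground-truth manifest records every planted feature.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import _placement
from .editors import BaseEditor, default_editors
from .editquant import BaseCounts, DEFAULT_SEQUENCING_ERROR
from .genome import (
    AcceptorSite,
    ExonRef,
    Genome,
    TranscriptModel,
    acceptor_of,
    exon_refs,
    revcomp,
    write_gtf,
)
from .skipquant import exon_sequences

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# fixed substream keys: genome, pileup, reads
_STREAM_GENOME, _STREAM_PILEUP, _STREAM_READS = 0, 1, 2


@dataclass(frozen=True)
class PlantedGuide:
    """Request: a PAM for ``editor`` placed so the acceptor C of inner exon
    ``exon_index`` of transcript ``transcript_index`` sits at protospacer
    position ``target_c_position``."""

    transcript_index: int
    exon_index: int
    editor: str
    target_c_position: int


@dataclass(frozen=True)
class PlantedOfftarget:
    """Request: a copy of planted guide ``guide_index`` elsewhere in the
    genome with ``n_mismatches`` protospacer mismatches."""

    guide_index: int
    n_mismatches: int
    strand: str = "+"


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    Default edit rate, error rate, depth, skip fraction and replicate sizes
    are the regimes observed in the amplicon/RNA sequencing experiments the
    package is built around (G>A 26.38% at depth ~5000, MiSeq error 0.383%,
    skip fraction 32.46%, 2000 units per replicate, ~10% junction-free
    units).
    """

    seed: int = 0
    n_transcripts: int = 2
    exons_per_transcript: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (60, 120)
    intron_length: tuple[int, int] = (80, 200)
    flank_length: int = 400
    editors: tuple[str, ...] = ("SpCas9-BE3",)
    planted_guides: tuple[PlantedGuide, ...] = ()
    planted_offtargets: tuple[PlantedOfftarget, ...] = ()
    edit_rate: float = 0.2638
    error_rate: float = DEFAULT_SEQUENCING_ERROR
    depth: int = 5000
    skip_fraction: float = 0.3246
    n_units: int = 2000
    filler_fraction: float = 0.10
    read_length: int = 100


@dataclass
class Fixture:
    """A generated toy genome with its annotation and ground truth."""

    spec: FixtureSpec
    genome: Genome
    transcripts: list[TranscriptModel]
    manifest: dict


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _concrete_pam(pattern: str, rng: np.random.Generator) -> str:
    from .editors import IUPAC

    # N positions drawn from A/C only: a planted PAM must not seed shifted
    # accidental matches (G feeds NGG/NGA/NGCG, T feeds NNNRRT)
    return "".join(
        str(rng.choice(["A", "C"])) if c == "N" else str(rng.choice(sorted(IUPAC[c])))
        for c in pattern
    )


class _MutableGenome:
    """Contig sequences as mutable character arrays during construction."""

    def __init__(self) -> None:
        self.contigs: dict[str, list[str]] = {}

    def write(self, contig: str, start: int, seq: str, strand: str = "+") -> None:
        if strand == "-":
            seq = revcomp(seq)
        self.contigs[contig][start : start + len(seq)] = list(seq)

    def read(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        seq = "".join(self.contigs[contig][start:end])
        return revcomp(seq) if strand == "-" else seq

    def freeze(self) -> Genome:
        return Genome({name: "".join(chars) for name, chars in self.contigs.items()})


def _build_transcript(
    rng: np.random.Generator, contig: str, strand: str, spec: FixtureSpec, index: int
) -> tuple[str, TranscriptModel]:
    """One contig holding one transcript; introns forced to GT...AG."""
    n_exons = int(rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1))
    exon_lens = rng.integers(spec.exon_length[0], spec.exon_length[1] + 1, size=n_exons)
    intron_lens = rng.integers(spec.intron_length[0], spec.intron_length[1] + 1, size=n_exons - 1)

    parts: list[str] = [_random_seq(rng, spec.flank_length)]
    sense_exons: list[tuple[int, int]] = []
    cursor = spec.flank_length
    for i, elen in enumerate(exon_lens):
        sense_exons.append((cursor, cursor + int(elen)))
        parts.append(_random_seq(rng, int(elen)))
        cursor += int(elen)
        if i < n_exons - 1:
            ilen = int(intron_lens[i])
            intron = list(_random_seq(rng, ilen))
            intron[:2] = ["G", "T"]
            intron[-2:] = ["A", "G"]
            parts.append("".join(intron))
            cursor += ilen
    parts.append(_random_seq(rng, spec.flank_length))
    sense_seq = "".join(parts)

    if strand == "+":
        contig_seq, exons = sense_seq, sense_exons
    else:
        total = len(sense_seq)
        contig_seq = revcomp(sense_seq)
        exons = [(total - e, total - s) for s, e in sense_exons]  # 5'->3' = descending start
    tx = TranscriptModel(
        transcript_id=f"TX{index + 1}",
        gene_id=f"GENE{index + 1}",
        contig=contig,
        strand=strand,
        exons=exons,
        coding=True,
    )
    return contig_seq, tx


def _protected_union(intervals: list[tuple[str, int, int]], contig: str, lo: int, hi: int) -> bool:
    return any(c == contig and lo < e and s < hi for c, s, e in intervals)


def _plant_guide(
    mg: _MutableGenome,
    genome_view: Genome,
    tx: TranscriptModel,
    req: PlantedGuide,
    editor: BaseEditor,
    rng: np.random.Generator,
    protected: list[tuple[str, int, int]],
) -> dict:
    exon = exon_refs(tx)[req.exon_index]
    acc = acceptor_of(exon, genome_view)
    if editor.profile[req.target_c_position] <= 0:
        raise ValueError(
            f"position {req.target_c_position} outside the {editor.name} editing window"
        )
    L, k = editor.protospacer_length, len(editor.pam_matcher)
    start, end, strand = _placement(acc, L, req.target_c_position)
    pam_lo, pam_hi = (start - k, start) if strand == "-" else (end, end + k)
    pam_seq = _concrete_pam(editor.pam, rng)
    mg.write(tx.contig, pam_lo, pam_seq, strand)
    # only the PAM bases (and the globally protected acceptor dinucleotide)
    # are load-bearing; the rest of the protospacer may be mutated when
    # scrubbing accidental PAMs and is re-read afterwards
    protected.append((tx.contig, pam_lo, pam_hi))
    protospacer = mg.read(tx.contig, start, end, strand)
    return {
        "transcript_id": tx.transcript_id,
        "exon_index": req.exon_index,
        "editor": editor.name,
        "contig": tx.contig,
        "acceptor_position": acc.position,
        "start": start,
        "end": end,
        "strand": strand,
        "protospacer": protospacer,
        "pam": pam_seq,
        "target_c_position": req.target_c_position,
        "predicted_efficiency": editor.profile[req.target_c_position],
    }


def _break_pam(
    mg: _MutableGenome,
    contig: str,
    pam_lo: int,
    strand: str,
    editor: BaseEditor,
    rng: np.random.Generator,
    protected: list[tuple[str, int, int]],
) -> bool:
    """Mutate one PAM base so the editor's primary pattern no longer matches."""
    matcher = editor.pam_matcher
    k = len(matcher)
    for j in range(k - 1, -1, -1):
        allowed = matcher.allowed[j]
        forbidden = sorted(set("ACGT") - allowed)
        if not forbidden:
            continue  # N position: no single-base fix here
        if strand == "+":
            gpos = pam_lo + j
        else:
            gpos = pam_lo + (k - 1 - j)  # strand-oriented j maps back
        if _protected_union(protected, contig, gpos, gpos + 1):
            continue
        preferred = [b for b in forbidden if b not in "G"] or forbidden
        base = str(rng.choice(preferred))
        mg.write(contig, gpos, base if strand == "+" else revcomp(base), "+")
        return True
    return False


def _scrub_unplanted_pams(
    mg: _MutableGenome,
    transcripts: list[TranscriptModel],
    editors: dict[str, BaseEditor],
    planted: set[tuple[str, int, str, int]],
    rng: np.random.Generator,
    protected: list[tuple[str, int, int]],
    max_passes: int = 50,
) -> None:
    """Remove accidental design-range PAM matches so the manifest is the
    complete set of designable guides on the fixture."""
    for _ in range(max_passes):
        dirty = False
        for tx in transcripts:
            for exon in exon_refs(tx):
                if not exon.is_inner:
                    continue
                acc = acceptor_of(exon, mg.freeze())
                for editor in editors.values():
                    L, k = editor.protospacer_length, len(editor.pam_matcher)
                    for p in editor.profile.positions:
                        key = (tx.contig, acc.position, editor.name, p)
                        if key in planted:
                            continue
                        start, end, strand = _placement(acc, L, p)
                        pam_lo, pam_hi = (start - k, start) if strand == "-" else (end, end + k)
                        if min(start, pam_lo) < 0 or max(end, pam_hi) > len(mg.contigs[tx.contig]):
                            continue
                        if mg.read(tx.contig, start, end, strand)[p - 1] != "C":
                            continue
                        pam_seq = mg.read(tx.contig, pam_lo, pam_hi, strand)
                        if editor.pam_matcher.matches(pam_seq):
                            if not _break_pam(mg, tx.contig, pam_lo, strand, editor, rng, protected):
                                raise RuntimeError("cannot break accidental PAM: all bases protected")
                            dirty = True
        if not dirty:
            return
    raise RuntimeError("PAM scrubbing did not converge")


def _plant_offtarget(
    mg: _MutableGenome,
    req: PlantedOfftarget,
    guide_entry: dict,
    editor: BaseEditor,
    rng: np.random.Generator,
    cursor: dict[str, int],
    protected: list[tuple[str, int, int]],
) -> dict:
    proto = guide_entry["protospacer"]
    L, k = len(proto), len(editor.pam_matcher)
    site = list(proto)
    positions = sorted(rng.choice(L, size=req.n_mismatches, replace=False) + 1) if req.n_mismatches else []
    for p in positions:
        site[p - 1] = str(rng.choice(sorted(set("ACGT") - {site[p - 1]})))
    site_seq = "".join(site)
    pam_seq = _concrete_pam(editor.pam, rng)

    contig = guide_entry["contig"]
    pos = cursor[contig]
    if pos + L + k + 5 > len(mg.contigs[contig]):
        raise ValueError("infeasible off-target placement: flank exhausted")
    cursor[contig] = pos + L + k + 10
    if req.strand == "+":
        start, end = pos, pos + L
        mg.write(contig, start, site_seq + pam_seq, "+")
    else:
        start, end = pos + k, pos + k + L
        mg.write(contig, pos, revcomp(site_seq + pam_seq), "+")
    protected.append((contig, pos, pos + L + k))
    return {
        "guide_index": req.guide_index,
        "contig": contig,
        "start": start,
        "end": end,
        "strand": req.strand,
        "site_sequence": site_seq,
        "pam": pam_seq,
        "n_mismatches": req.n_mismatches,
        "mismatch_positions": [int(p) for p in positions],
    }


def make_toy_genome(
    spec: FixtureSpec, editors: dict[str, BaseEditor] | None = None
) -> Fixture:
    """Build the toy genome, annotation and ground-truth manifest.

    Post-conditions: every intron ends in AG (and starts with GT); the
    designable guides at every acceptor of the requested editors are exactly
    the planted ones; planted off-target sites sit in the intergenic flank
    with the requested mismatch counts.
    """
    if editors is None:
        editors = default_editors()
    editors = {name: editors[name] for name in spec.editors}
    rng = _rng(spec.seed, _STREAM_GENOME)

    mg = _MutableGenome()
    transcripts: list[TranscriptModel] = []
    for i in range(spec.n_transcripts):
        contig = f"chr{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        seq, tx = _build_transcript(rng, contig, strand, spec, i)
        mg.contigs[contig] = list(seq)
        transcripts.append(tx)

    protected: list[tuple[str, int, int]] = []
    # protect every acceptor dinucleotide and donor dinucleotide
    for tx in transcripts:
        for exon in exon_refs(tx):
            if exon.is_inner or exon.exon_index > 0:
                if exon.strand == "+":
                    protected.append((tx.contig, exon.start - 2, exon.start))
                else:
                    protected.append((tx.contig, exon.end, exon.end + 2))

    guide_entries: list[dict] = []
    planted_keys: set[tuple[str, int, str, int]] = set()
    for req in spec.planted_guides:
        tx = transcripts[req.transcript_index]
        entry = _plant_guide(mg, mg.freeze(), tx, req, editors[req.editor], rng, protected)
        guide_entries.append(entry)
        planted_keys.add((entry["contig"], entry["acceptor_position"], req.editor, req.target_c_position))

    _scrub_unplanted_pams(mg, transcripts, editors, planted_keys, rng, protected)
    # protospacer sequences may have shifted during scrubbing; re-read
    for entry in guide_entries:
        entry["protospacer"] = mg.read(entry["contig"], entry["start"], entry["end"], entry["strand"])

    cursor = {tx.contig: len(mg.contigs[tx.contig]) - spec.flank_length + 20 for tx in transcripts}
    offtarget_entries = [
        _plant_offtarget(mg, req, guide_entries[req.guide_index], editors[guide_entries[req.guide_index]["editor"]], rng, cursor, protected)
        for req in spec.planted_offtargets
    ]

    genome = mg.freeze()
    manifest = {
        "seed": spec.seed,
        "editors": list(spec.editors),
        "guides": guide_entries,
        "offtargets": offtarget_entries,
        "transcripts": [
            {
                "transcript_id": tx.transcript_id,
                "contig": tx.contig,
                "strand": tx.strand,
                "exons": [list(e) for e in tx.exons],
            }
            for tx in transcripts
        ],
    }
    return Fixture(spec=spec, genome=genome, transcripts=transcripts, manifest=manifest)


def simulate_pileup(
    spec: FixtureSpec,
    genome: Genome,
    contig: str,
    region: tuple[int, int],
    edited: dict[int, tuple[str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> BaseCounts:
    """Multinomial per-position pileup over ``region`` (0-based half-open).

    ``edited`` maps genomic position -> (alternative base on the reference
    strand, true edit rate).  Everywhere, the sequencing error rate is
    spread uniformly over the three non-reference bases.
    """
    import pandas as pd

    if rng is None:
        rng = _rng(spec.seed, _STREAM_PILEUP)
    e = spec.error_rate
    edited = edited or {}
    rows = {}
    refs = {}
    for pos in range(*region):
        ref = genome.fetch(contig, pos, pos + 1, "+")
        probs = dict.fromkeys("ACGT", e / 3)
        probs[ref] = 1.0 - e
        if pos in edited:
            alt, rate = edited[pos]
            if rate + e > 1:
                raise ValueError("edit rate plus error exceeds 1")
            probs[alt] += rate
            probs[ref] -= rate
        draw = rng.multinomial(spec.depth, [probs[b] for b in "ACGT"])
        rows[pos] = dict(zip("ACGT", (int(x) for x in draw)), N=0)
        refs[pos] = ref
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "position"
    table.insert(0, "ref", pd.Series(refs))
    return BaseCounts(contig=contig, table=table)


def acceptor_pileup(
    spec: FixtureSpec,
    fixture: Fixture,
    guide_entry: dict,
    pad: int = 25,
    rng: np.random.Generator | None = None,
) -> BaseCounts:
    """Pileup of an amplicon around a planted guide's acceptor, with the
    acceptor base edited at ``spec.edit_rate`` (G>A on the transcript
    strand; C>T on the reference strand for minus-strand transcripts)."""
    g = guide_entry["acceptor_position"]
    contig = guide_entry["contig"]
    ref = fixture.genome.fetch(contig, g, g + 1, "+")
    alt = {"G": "A", "C": "T"}[ref]
    return simulate_pileup(
        spec,
        fixture.genome,
        contig,
        (g - pad, g + pad),
        edited={g: (alt, spec.edit_rate)},
        rng=rng,
    )


def simulate_junction_units(
    spec: FixtureSpec,
    transcript: TranscriptModel,
    skip_exon_index: int,
    genome: Genome,
    rng: np.random.Generator | None = None,
    skip_fraction: float | None = None,
    n_units: int | None = None,
    probe_flank: int = 20,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Paired junction-spanning units at a known skip fraction.

    Each unit is skipped with probability ``skip_fraction`` (canonical
    otherwise); a ``filler_fraction`` of units carry random junction-free
    sequence to exercise the discard rule.  One mate is guaranteed to span
    the relevant junction with at least ``probe_flank`` nt on each side.
    Returns (units, true_labels).
    """
    if rng is None:
        rng = _rng(spec.seed, _STREAM_READS)
    f = spec.skip_fraction if skip_fraction is None else skip_fraction
    n = spec.n_units if n_units is None else n_units
    rl = spec.read_length
    if rl < 2 * probe_flank:
        raise ValueError("read length must cover a full probe")

    seqs = exon_sequences(transcript, genome)
    i = skip_exon_index
    canonical_mrna = "".join(seqs)
    skipped_mrna = "".join(seqs[:i] + seqs[i + 1 :])
    j_canon = sum(len(s) for s in seqs[:i])
    j_skip = j_canon

    units: list[tuple[str, str]] = []
    labels: list[str] = []
    for _ in range(n):
        if rng.random() < spec.filler_fraction:
            units.append((_random_seq(rng, rl), _random_seq(rng, rl)))
            labels.append("discarded")
            continue
        is_skip = rng.random() < f
        template, j = (skipped_mrna, j_skip) if is_skip else (canonical_mrna, j_canon)
        lo = max(0, j + probe_flank - rl)
        hi = min(j - probe_flank, len(template) - rl)
        start = int(rng.integers(lo, hi + 1))
        frag_len = rl + int(rng.integers(0, rl // 2 + 1))
        fend = min(len(template), start + frag_len)
        mate1 = template[start : start + rl]
        mate2 = revcomp(template[max(0, fend - rl) : fend])
        units.append((mate1, mate2))
        labels.append("skipped" if is_skip else "canonical")
    return units, labels


def write_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq_pair(units: Sequence[tuple[str, str]], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, (m1, m2) in enumerate(units):
            f1.write(f"@unit{i}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@unit{i}/2\n{m2}\n+\n{'I' * len(m2)}\n")


def write_fixture(fixture: Fixture, outdir) -> None:
    """Write FASTA, GTF and the ground-truth manifest into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fixture.genome, outdir / "genome.fa")
    write_gtf(fixture.transcripts, outdir / "annotation.gtf")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(fixture.manifest, fh, indent=2)
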