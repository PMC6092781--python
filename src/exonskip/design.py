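"""Enumerate base-editor sgRNAs that disrupt a splice-acceptor guanosine.

The conserved acceptor G sits on the transcript strand, so the editable
cytidine is its complement on the *antisense* strand.  A guide is therefore
placed on the antisense strand such that this C falls at a protospacer
position where the editor's deaminase is active, with a matching PAM
immediately 3' of the protospacer on that strand.

Geometry (0-based genomic coordinates, protospacer positions 1-based with
PAM-distal = 1):

* transcript on ``+``: guide on ``-``; a protospacer occupying ``[s, s+L)``
  places position ``p`` at genomic coordinate ``s + L - p``, PAM at
  ``[s - k, s)``.
* transcript on ``-``: guide on ``+``; position ``p`` sits at ``s + p - 1``,
  PAM at ``[s+L, s+L+k)``.

The first exonic base is one step 3' of the acceptor G on the transcript
strand, i.e. at protospacer position ``p - 1``; when that base is a G inside
the active window the editor may also convert it (a bystander edit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .editors import BaseEditor
from .genome import AcceptorSite, Genome

logger = logging.getLogger(__name__)


@dataclass
class GuideCandidate:
    """One sgRNA placement disrupting one splice acceptor."""

    acceptor: AcceptorSite
    editor: BaseEditor
    protospacer: str  # on the guide (antisense) strand, 5'->3'
    pam_observed: str
    target_c_position: int  # protospacer position of the C opposite the acceptor G
    predicted_efficiency: float
    bystander: bool
    contig: str
    start: int  # genomic interval of the protospacer, 0-based half-open
    end: int
    strand: str  # guide strand
    top_offtarget_score: float | None = None

    @property
    def guide_id(self) -> str:
        ex = self.acceptor.exon
        return f"{ex.transcript_id}:{ex.exon_index}:{self.editor.name}:{self.contig}:{self.start}{self.strand}"

    @property
    def c_to_pam_distance(self) -> int:
        return self.editor.c_to_pam_distance(self.target_c_position)


def _placement(acceptor: AcceptorSite, length: int, position: int) -> tuple[int, int, str]:
    """Genomic interval and strand of a protospacer putting the edited C at
    protospacer ``position``."""
    g = acceptor.position
    if acceptor.strand == "+":
        start = g - length + position
        return start, start + length, "-"
    start = g - position + 1
    return start, start + length, "+"


def _first_exonic_base(acceptor: AcceptorSite, genome: Genome) -> str:
    ex = acceptor.exon
    if acceptor.strand == "+":
        return genome.fetch(ex.contig, ex.start, ex.start + 1, "+")
    return genome.fetch(ex.contig, ex.end - 1, ex.end, "-")


def bystander_flag(candidate: GuideCandidate, genome: Genome) -> bool:
    """True when the exon's first base is a G whose antisense C lies in the
    editor's active window for this placement (position ``p - 1``)."""
    if _first_exonic_base(candidate.acceptor, genome) != "G":
        return False
    pos = candidate.target_c_position - 1
    return pos >= 1 and candidate.editor.profile[pos] > 0


def enumerate_guides(
    acceptor: AcceptorSite,
    genome: Genome,
    editor: BaseEditor,
    include_secondary_pams: bool = False,
) -> list[GuideCandidate]:
    """All valid guide placements for one acceptor and one editor.

    One candidate per profile position with non-zero efficiency where the
    protospacer fits on the contig, carries a C at that position (it will,
    whenever the acceptor base really is G) and has a matching PAM.
    Sorted by predicted efficiency (desc), then target position (asc), then
    genomic start.
    """
    matchers = [editor.pam_matcher]
    if include_secondary_pams:
        matchers += [m for m in editor.scan_pam_matchers(True)[1:]]
    k = len(editor.pam_matcher)
    L = editor.protospacer_length
    contig_len = len(genome.sequences[acceptor.contig])

    out: list[GuideCandidate] = []
    for p in editor.profile.positions:
        start, end, strand = _placement(acceptor, L, p)
        if strand == "-":
            pam_lo, pam_hi = start - k, start
        else:
            pam_lo, pam_hi = end, end + k
        if min(start, pam_lo) < 0 or max(end, pam_hi) > contig_len:
            logger.debug("placement p=%d for %s skipped: outside contig", p, acceptor)
            continue
        protospacer = genome.fetch(acceptor.contig, start, end, strand)
        if protospacer[p - 1] != "C":
            continue
        pam_seq = genome.fetch(acceptor.contig, pam_lo, pam_hi, strand)
        if not any(m.matches(pam_seq) for m in matchers):
            continue
        cand = GuideCandidate(
            acceptor=acceptor,
            editor=editor,
            protospacer=protospacer,
            pam_observed=pam_seq,
            target_c_position=p,
            predicted_efficiency=editor.profile[p],
            bystander=False,
            contig=acceptor.contig,
            start=start,
            end=end,
            strand=strand,
        )
        cand.bystander = bystander_flag(cand, genome)
        out.append(cand)
    out.sort(key=lambda c: (-c.predicted_efficiency, c.target_c_position, c.start))
    return out


def design_guides(
    acceptors: Iterable[AcceptorSite],
    genome: Genome,
    editors: Iterable[BaseEditor],
    include_secondary_pams: bool = False,
) -> list[GuideCandidate]:
    """Enumerate guides across many acceptors and editors."""
    out: list[GuideCandidate] = []
    for acceptor in acceptors:
        for editor in editors:
            out.extend(enumerate_guides(acceptor, genome, editor, include_secondary_pams))
    return out


def targetability_summary(
    acceptors: Sequence[AcceptorSite],
    genome: Genome,
    editors: Iterable[BaseEditor],
    efficiency_thresholds: Sequence[float],
    offtarget_cutoffs: Sequence[float],
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Per-editor counts of acceptors with >=1 surviving guide.

    A guide survives a (threshold, cutoff) pair when its predicted
    efficiency is >= the threshold and its top off-target score is <= the
    cutoff.  Counts are non-increasing as either filter tightens.
    """
    from .offtarget import annotate_top_scores

    rows = []
    for editor in editors:
        per_acceptor: list[list[GuideCandidate]] = []
        for acc in acceptors:
            guides = enumerate_guides(acc, genome, editor)
            annotate_top_scores(guides, genome, max_mismatches=max_mismatches)
            per_acceptor.append(guides)
        for thr in efficiency_thresholds:
            for cut in offtarget_cutoffs:
                n = sum(
                    any(
                        g.predicted_efficiency >= thr and g.top_offtarget_score <= cut
                        for g in guides
                    )
                    for guides in per_acceptor
                )
                rows.append(
                    {
                        "editor": editor.name,
                        "efficiency_threshold": thr,
                        "offtarget_cutoff": cut,
                        "n_targetable": n,
                    }
                )
    return pd.DataFrame(rows)


def guides_to_dataframe(guides: Iterable[GuideCandidate]) -> pd.DataFrame:
    rows = []
    for g in guides:
        ex = g.acceptor.exon
        rows.append(
            {
                "guide_id": g.guide_id,
                "gene_id": ex.gene_id,
                "transcript_id": ex.transcript_id,
                "exon_index": ex.exon_index,
                "editor": g.editor.name,
                "contig": g.contig,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "protospacer": g.protospacer,
                "pam": g.pam_observed,
                "target_c_position": g.target_c_position,
                "c_to_pam_distance": g.c_to_pam_distance,
                "predicted_efficiency": g.predicted_efficiency,
                "bystander": g.bystander,
                "acceptor_dinucleotide": g.acceptor.dinucleotide,
                "top_offtarget_score": g.top_offtarget_score,
            }
        )
    return pd.DataFrame(rows)


def guides_to_tsv(guides: Iterable[GuideCandidate], path) -> None:
    guides_to_dataframe(guides).to_csv(path, sep="\t", index=False)


def guides_to_bed(guides: Iterable[GuideCandidate], path) -> None:
    """BED6 of protospacer intervals; score = round(100 x efficiency)."""
    with open(path, "w") as fh:
        for g in guides:
            ex = g.acceptor.exon
            name = f"{ex.gene_id or ex.transcript_id}:{ex.exon_index}:{g.editor.name}"
            score = round(100 * g.predicted_efficiency)
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{name}\t{score}\t{g.strand}\n")
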