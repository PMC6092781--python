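"""Genome-wide near-match enumeration and single-site off-target scoring.

A guide with close matches elsewhere in the genome risks unintended edits.
Candidate off-target sites are all protospacer-length placements, on either
strand, with a compatible PAM and at most ``max_mismatches`` mismatches
against the guide.  Each site gets a 0-100 similarity score (100 = perfect
match); a guide whose best off-target site scores above a cutoff (default
10) is discarded.

The per-site score follows the experimentally derived single-site scheme of
Hsu et al. 2013: mismatches are penalised position-dependently (PAM-proximal
mismatches weigh more), clustered mismatches less than spread-out ones, and
each additional mismatch quadratically::

    score = 100 * prod_p (1 - w[p])
                * 1 / (((L-1 - dbar) / (L-1)) * 4 + 1)   # only for m >= 2
                * 1 / m**2                               # only for m >= 2

where ``w`` is the per-position weight vector, ``dbar`` the mean pairwise
distance between mismatched positions and ``m`` the mismatch count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .design import GuideCandidate
from .editors import PamMatcher
from .genome import Genome, revcomp

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_N_CODE = 4


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pam_table(matcher: PamMatcher) -> np.ndarray:
    """(k, 5) boolean lookup; code 4 (N in genome) never matches."""
    table = np.zeros((len(matcher), 5), dtype=bool)
    for j, allowed in enumerate(matcher.allowed):
        for base in allowed:
            table[j, _ENCODE[ord(base)]] = True
    return table


@dataclass(frozen=True)
class OfftargetSite:
    contig: str
    start: int  # 0-based half-open genomic interval of the protospacer
    end: int
    strand: str
    site_sequence: str  # strand-oriented, protospacer length
    pam_sequence: str
    n_mismatches: int
    mismatch_positions: tuple[int, ...]  # 1-based, PAM-distal = 1
    score: float


def load_mismatch_weights(path=None) -> dict[int, list[float]]:
    """Per-position mismatch penalty vectors keyed by protospacer length."""
    if path is None:
        text = resources.files("exonskip.data").joinpath("mismatch_weights.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = json.loads(text)
    return {int(k): [float(x) for x in v] for k, v in data["weights"].items()}


def mismatched_positions(guide_seq: str, site_seq: str) -> tuple[int, ...]:
    """1-based PAM-distal positions where the site differs from the guide.

    An N in either sequence always counts as a mismatch.
    """
    if len(guide_seq) != len(site_seq):
        raise ValueError("guide and site sequences differ in length")
    return tuple(
        i + 1
        for i, (a, b) in enumerate(zip(guide_seq, site_seq))
        if a != b or a == "N" or b == "N"
    )


def site_score(guide_seq: str, site, weights: Sequence[float]) -> float:
    """0-100 similarity score of one candidate site against its guide."""
    site_seq = site.site_sequence if isinstance(site, OfftargetSite) else str(site)
    if len(weights) != len(guide_seq):
        raise ValueError("weight vector length must equal protospacer length")
    mm = mismatched_positions(guide_seq, site_seq)
    m = len(mm)
    if m == 0:
        return 100.0
    score = 1.0
    for p in mm:
        score *= 1.0 - weights[p - 1]
    if m >= 2:
        L = len(guide_seq)
        pairs = [(b - a) for i, a in enumerate(mm) for b in mm[i + 1:]]
        dbar = sum(pairs) / len(pairs)
        score *= 1.0 / (((L - 1 - dbar) / (L - 1)) * 4 + 1)
        score *= 1.0 / (m * m)
    return 100.0 * score


def _scan_oriented(
    seq_enc: np.ndarray,
    guide_enc: np.ndarray,
    pam_tables: list[np.ndarray],
    max_mismatches: int,
) -> list[tuple[int, int, int]]:
    """Offsets (offset, n_mm, pam_index) in a strand-oriented sequence where
    the protospacer window has <= max_mismatches and a PAM follows."""
    L = guide_enc.size
    if seq_enc.size < L:
        return []
    windows = sliding_window_view(seq_enc, L)
    mism = ((windows != guide_enc) | (windows == _N_CODE) | (guide_enc == _N_CODE)).sum(axis=1)
    cand = np.nonzero(mism <= max_mismatches)[0]
    out: list[tuple[int, int, int]] = []
    for off in cand:
        for pi, table in enumerate(pam_tables):
            k = table.shape[0]
            if off + L + k > seq_enc.size:
                continue
            pam = seq_enc[off + L : off + L + k]
            if table[np.arange(k), pam].all():
                out.append((int(off), int(mism[off]), pi))
                break
    return out


def scan_offtargets(
    guide: GuideCandidate,
    genome: Genome,
    max_mismatches: int = 2,
    pam_matchers: Sequence[PamMatcher] | None = None,
    weights: Sequence[float] | None = None,
    include_secondary_pams: bool = True,
) -> list[OfftargetSite]:
    """Every genomic placement (both strands) with a compatible PAM and at
    most ``max_mismatches`` mismatches, the on-target site included.

    By default the scan accepts the editor's secondary PAMs too (off-target
    binding tolerates weaker PAMs even when the design did not use them).
    """
    if pam_matchers is None:
        pam_matchers = guide.editor.scan_pam_matchers(include_secondary_pams)
    if weights is None:
        weights = load_mismatch_weights()[guide.editor.protospacer_length]
    guide_enc = _encode(guide.protospacer)
    pam_tables = [_pam_table(m) for m in pam_matchers]

    sites: list[OfftargetSite] = []
    for contig, seq in genome.sequences.items():
        M = len(seq)
        fwd = _encode(seq)
        rc = _encode(revcomp(seq))
        L = guide_enc.size
        for strand, enc in (("+", fwd), ("-", rc)):
            for off, n_mm, pi in _scan_oriented(enc, guide_enc, pam_tables, max_mismatches):
                k = pam_tables[pi].shape[0]
                if strand == "+":
                    start, end = off, off + L
                    site_seq = seq[start:end]
                    pam_seq = seq[end : end + k]
                else:
                    start, end = M - off - L, M - off
                    site_seq = revcomp(seq[start:end])
                    pam_seq = revcomp(seq[start - k : start])
                mm = mismatched_positions(guide.protospacer, site_seq)
                sites.append(
                    OfftargetSite(
                        contig=contig,
                        start=start,
                        end=end,
                        strand=strand,
                        site_sequence=site_seq,
                        pam_sequence=pam_seq,
                        n_mismatches=len(mm),
                        mismatch_positions=mm,
                        score=site_score(guide.protospacer, site_seq, weights),
                    )
                )
    sites.sort(key=lambda s: (-s.score, s.contig, s.start, s.strand))
    return sites


def _is_on_target(guide: GuideCandidate, site: OfftargetSite) -> bool:
    return (
        site.contig == guide.contig
        and site.start == guide.start
        and site.strand == guide.strand
    )


def guide_top_score(guide: GuideCandidate, sites: Iterable[OfftargetSite]) -> float:
    """Highest off-target score among sites other than the on-target locus;
    0 when the guide has no off-target site at all."""
    scores = [s.score for s in sites if not _is_on_target(guide, s)]
    return max(scores) if scores else 0.0


def annotate_top_scores(
    guides: Iterable[GuideCandidate],
    genome: Genome,
    max_mismatches: int = 2,
    include_secondary_pams: bool = True,
) -> None:
    """Scan each guide and set its ``top_offtarget_score`` in place."""
    for g in guides:
        sites = scan_offtargets(
            g, genome, max_mismatches=max_mismatches,
            include_secondary_pams=include_secondary_pams,
        )
        g.top_offtarget_score = guide_top_score(g, sites)


def filter_by_specificity(
    guides: Sequence[GuideCandidate], cutoff: float = 10.0
) -> list[GuideCandidate]:
    """Keep guides whose top off-target score is <= cutoff (a top score of
    exactly the cutoff survives; only strictly greater is removed)."""
    for g in guides:
        if g.top_offtarget_score is None:
            raise ValueError(f"guide {g.guide_id} has no top_offtarget_score; run annotate_top_scores")
    return [g for g in guides if g.top_offtarget_score <= cutoff]


def offtargets_to_dataframe(guide: GuideCandidate, sites: Iterable[OfftargetSite]):
    import pandas as pd

    return pd.DataFrame(
        {
            "guide_id": guide.guide_id,
            "contig": s.contig,
            "start": s.start,
            "end": s.end,
            "strand": s.strand,
            "site_sequence": s.site_sequence,
            "pam": s.pam_sequence,
            "n_mismatches": s.n_mismatches,
            "score": s.score,
        }
        for s in sites
    )
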