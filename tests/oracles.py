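"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the package's vectorised scanning code and
coordinate arithmetic: guides and off-target sites are found by explicit
sliding-window search with per-character comparison, and tail probabilities
come from log-gamma summation and the complementary error function.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def iupac_match(pattern: str, kmer: str, table: dict[str, frozenset]) -> bool:
    if len(pattern) != len(kmer):
        return False
    return all(b in table[p] and b != "N" for p, b in zip(pattern, kmer))


def window(seq: str, start: int, length: int, strand: str):
    """Strand-oriented k-mer at genomic [start, start+length); None if out."""
    if start < 0 or start + length > len(seq):
        return None
    sub = seq[start : start + length]
    return rc(sub) if strand == "-" else sub


def brute_force_guides(acceptor, genome, editor, iupac, include_secondary=False):
    """Exhaustive both-strand sliding-window guide search.

    Returns the set of (start, end, strand, target_c_position) placements
    whose protospacer covers the acceptor's antisense C at a non-zero
    profile position, carries a C there, and has an adjacent matching PAM.
    """
    pams = [editor.pam] + (list(editor.secondary_pams) if include_secondary else [])
    L = editor.protospacer_length
    seq = genome.sequences[acceptor.contig]
    found = set()
    for strand in "+-":
        for start in range(0, len(seq) - L + 1):
            proto = window(seq, start, L, strand)
            for p in editor.profile.positions:
                gpos = start + p - 1 if strand == "+" else start + L - p
                if gpos != acceptor.position:
                    continue
                if proto[p - 1] != "C":
                    continue
                for pam_pat in pams:
                    k = len(pam_pat)
                    pam_start = start + L if strand == "+" else start - k
                    pam = window(seq, pam_start, k, strand)
                    if pam is not None and iupac_match(pam_pat, pam, iupac):
                        found.add((start, start + L, strand, p))
                        break
    return found


def brute_force_offtargets(protospacer, genome, pam_patterns, iupac, max_mm=2):
    """Exhaustive Hamming scan: set of (contig, start, end, strand, n_mm)."""
    L = len(protospacer)
    found = set()
    for contig, seq in genome.sequences.items():
        for strand in "+-":
            for start in range(0, len(seq) - L + 1):
                site = window(seq, start, L, strand)
                mm = 0
                for a, b in zip(protospacer, site):
                    if a != b or a == "N" or b == "N":
                        mm += 1
                        if mm > max_mm:
                            break
                if mm > max_mm:
                    continue
                for pat in pam_patterns:
                    k = len(pat)
                    pam_start = start + L if strand == "+" else start - k
                    pam = window(seq, pam_start, k, strand)
                    if pam is not None and iupac_match(pat, pam, iupac):
                        found.add((contig, start, start + L, strand, mm))
                        break
    return found


def binom_tail_upper(k: int, n: int, p: float) -> float:
    """P(X >= k | n, p) by log-gamma term summation (exact to ~1e-15)."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if p == 0.0:
        return 0.0
    terms = []
    lp, lq = math.log(p), math.log1p(-p)
    for i in range(k, n + 1):
        lc = math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
        terms.append(math.exp(lc + i * lp + (n - i) * lq))
    return min(1.0, math.fsum(terms))


def normal_two_sided_p(z: float) -> float:
    """Two-sided normal p via the complementary error function."""
    return math.erfc(abs(z) / math.sqrt(2.0))


def wald_z(k1, n1, k2, n2) -> float:
    p1, p2 = k1 / n1, k2 / n2
    return (p1 - p2) / math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)


def clopper_pearson_by_bisection(k: int, n: int, confidence: float = 0.95):
    """Invert the exact binomial tails by bisection (no beta quantiles)."""
    alpha = 1 - confidence

    def bisect(f, lo, hi, target):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    # both tails are increasing in p: P(X>=k|low) = alpha/2 and
    # P(X>=k+1|high) = 1 - alpha/2 (i.e. P(X<=k|high) = alpha/2)
    low = 0.0 if k == 0 else bisect(lambda p: binom_tail_upper(k, n, p), 0.0, 1.0, alpha / 2)
    high = (
        1.0
        if k == n
        else bisect(lambda p: binom_tail_upper(k + 1, n, p), 0.0, 1.0, 1 - alpha / 2)
    )
    return low, high


def mirror_transcripts(transcripts, genome):
    """Transcript models re-expressed on the reverse-complemented genome."""
    from exonskip.genome import TranscriptModel

    out = []
    for tx in transcripts:
        total = len(genome.sequences[tx.contig])
        strand = "-" if tx.strand == "+" else "+"
        exons = [(total - e, total - s) for s, e in tx.exons]
        out.append(
            TranscriptModel(
                transcript_id=tx.transcript_id,
                gene_id=tx.gene_id,
                contig=tx.contig,
                strand=strand,
                exons=exons,
                coding=tx.coding,
            )
        )
    return out
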