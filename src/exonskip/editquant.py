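"""Quantify base-editing outcomes from per-position base counts.

Editing efficiency at a locus is the fraction of reads carrying the
substituted base.  Two statistical procedures are provided:

* a two-tailed Wald test for equal binomial proportions between a control
  and an edited sample (on-target calls), and
* a one-sided binomial test against the sequencing error rate as background
  (off-target calls), at a stringent default cutoff of 1e-5.

p-values are also reported in log10 space: deeply sequenced amplicons
routinely drive them below the smallest representable double, and a bound
("p < 1e-323") is more honest than a hard 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T", "N")

#: sequencing error rate of the MiSeq platform estimated from control
#: amplicons (fraction of alternative-allele depth); used as the background
#: conversion probability when no control sample is supplied
DEFAULT_SEQUENCING_ERROR = 0.00383

_LN10 = math.log(10)


@dataclass
class BaseCounts:
    """Per-position A/C/G/T/N counts over one contig region.

    ``table`` is indexed by 0-based genomic position with columns
    A, C, G, T, N (counts; may be fractional after replicate averaging)
    and ``ref`` (reference base).
    """

    contig: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(BASES) - set(self.table.columns)
        if missing or "ref" not in self.table.columns:
            raise ValueError(f"counts table lacks columns {missing | {'ref'}}")
        if (self.table[list(BASES)].to_numpy() < 0).any():
            raise ValueError("negative base counts")

    def depth(self, position: int) -> float:
        return float(self.table.loc[position, list(BASES)].sum())

    @property
    def positions(self) -> list[int]:
        return list(self.table.index)


def read_pileup_tsv(path) -> BaseCounts:
    """Read a pileup table: contig, 1-based position, ref, A, C, G, T, N."""
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "pos", "ref", *BASES}
    if not required.issubset(df.columns):
        raise ValueError(f"pileup TSV must have columns {sorted(required)}")
    contigs = df["contig"].unique()
    if len(contigs) != 1:
        raise ValueError("pileup TSV must cover a single contig")
    table = df.set_index(df["pos"] - 1)[["ref", *BASES]]
    table.index.name = "position"
    return BaseCounts(contig=str(contigs[0]), table=table)


def write_pileup_tsv(counts: BaseCounts, path) -> None:
    df = counts.table.reset_index()
    df.insert(0, "contig", counts.contig)
    df["pos"] = df.pop("position") + 1
    df[["contig", "pos", "ref", *BASES]].to_csv(path, sep="\t", index=False)


def count_bases_sam(path, genome, region: tuple[str, int, int]) -> BaseCounts:
    """Tally per-position base counts from a SAM/BAM over a region.

    Streams primary alignments and uses their aligned pairs, so a plain
    coordinate-unsorted SAM works; deletions and clipped bases contribute
    nothing.  ``region`` is (contig, start, end), 0-based half-open.
    """
    contig, start, end = region
    tallies = {pos: dict.fromkeys(BASES, 0) for pos in range(start, end)}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if fh.get_reference_name(read.reference_id) != contig:
                continue
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if start <= rpos < end:
                    base = seq[qpos].upper()
                    tallies[rpos][base if base in BASES else "N"] += 1
    table = pd.DataFrame.from_dict(tallies, orient="index")
    table.index.name = "position"
    table["ref"] = [genome.fetch(contig, p, p + 1, "+") for p in table.index]
    counts = BaseCounts(contig=contig, table=table[["ref", *BASES]])
    uncovered = [p for p in counts.positions if counts.depth(p) == 0]
    if uncovered:
        logger.warning("%d position(s) in %s:%d-%d have zero coverage", len(uncovered), contig, start, end)
    return counts


def merge_replicates(replicates: Sequence[BaseCounts]) -> BaseCounts:
    """Average replicate tables position-wise.

    Per-position base *fractions* are averaged across replicates and
    rescaled by the mean depth, so merged counts may be fractional; with
    equal depths this coincides with averaging raw counts.
    """
    if not replicates:
        raise ValueError("no replicates to merge")
    first = replicates[0]
    if any(r.contig != first.contig or list(r.positions) != list(first.positions) for r in replicates):
        raise ValueError("replicates must cover the same contig and positions")
    mats = np.stack([r.table[list(BASES)].to_numpy(dtype=float) for r in replicates])
    depths = mats.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = np.where(depths > 0, mats / depths, 0.0)
    mean_frac = fracs.mean(axis=0)
    mean_depth = depths[:, :, 0].mean(axis=0)
    merged = mean_frac * mean_depth[:, None]
    table = pd.DataFrame(merged, index=first.table.index, columns=list(BASES))
    table.insert(0, "ref", first.table["ref"].to_numpy())
    return BaseCounts(contig=first.contig, table=table)


def modification_rates(counts: BaseCounts, position: int) -> dict[str, float]:
    """Substitution rates at one position: {"G>A": 0.26, ...} plus "ref_fraction"."""
    row = counts.table.loc[position]
    depth = float(sum(row[b] for b in BASES))
    if depth == 0:
        raise ValueError(f"zero depth at position {position}")
    ref = row["ref"]
    rates = {
        f"{ref}>{b}": float(row[b]) / depth
        for b in ("A", "C", "G", "T")
        if b != ref
    }
    rates["ref_fraction"] = float(row[ref]) / depth if ref in BASES else 0.0
    return rates


@dataclass(frozen=True)
class WaldResult:
    p_value: float
    z: float
    log10_p: float

    def __float__(self) -> float:
        return self.p_value


def wald_two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> WaldResult:
    """Two-tailed Wald test for equal binomial proportions.

    z = (p1 - p2) / sqrt(p1(1-p1)/n1 + p2(1-p2)/n2); two-sided p from the
    standard normal.  When both sample variances vanish (each proportion 0
    or 1): p = 1 if the proportions are equal, otherwise the pooled-variance
    z is used (logged).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    if var == 0:
        if p1 == p2:
            return WaldResult(p_value=1.0, z=0.0, log10_p=0.0)
        logger.info("degenerate Wald variance; falling back to pooled variance")
        pp = (k1 + k2) / (n1 + n2)
        var = pp * (1 - pp) * (1 / n1 + 1 / n2)
    z = (p1 - p2) / math.sqrt(var)
    log_p = math.log(2) + stats.norm.logsf(abs(z))
    return WaldResult(
        p_value=min(1.0, 2 * stats.norm.sf(abs(z))),
        z=z,
        log10_p=min(0.0, log_p / _LN10),
    )


def estimate_error_rate(
    counts: BaseCounts,
    positions: Iterable[int] | None = None,
    pooled: bool = False,
) -> float:
    """Sequencing error rate from a control sample.

    Default: the unweighted mean over covered positions of the fraction of
    non-reference depth.  With ``pooled`` the pooled-count estimate (total
    non-reference / total depth) is returned instead.
    """
    idx = list(positions) if positions is not None else counts.positions
    fracs = []
    tot_alt = tot_depth = 0.0
    for pos in idx:
        row = counts.table.loc[pos]
        depth = float(sum(row[b] for b in BASES))
        if depth == 0:
            continue
        ref = row["ref"]
        alt = depth - (float(row[ref]) if ref in BASES else 0.0)
        fracs.append(alt / depth)
        tot_alt += alt
        tot_depth += depth
    if not fracs:
        raise ValueError("no covered positions in control counts")
    if pooled:
        return tot_alt / tot_depth
    return float(np.mean(fracs))


@dataclass(frozen=True)
class EditCall:
    position: int  # 0-based genomic
    substitution: str  # e.g. "G>A"
    depth: float
    rate: float
    p_value: float
    log10_p: float
    significant: bool


def binomial_excess_log10p(k, n, p0: float) -> np.ndarray:
    """log10 of the upper-tail binomial p-value P(X >= k | n, p0).

    Where the survival function underflows double precision, the tail is
    re-summed in log space so extreme signals keep a finite, comparable
    log10 p instead of collapsing to -inf.
    """
    from scipy.special import logsumexp

    k = np.atleast_1d(np.asarray(k, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    with np.errstate(divide="ignore"):
        lp = stats.binom.logsf(k - 1, n, p0)
    for i in np.nonzero(~np.isfinite(lp) & (k > 0))[0]:
        tail = np.arange(k[i], n[i] + 1)
        lp[i] = logsumexp(stats.binom.logpmf(tail, n[i], p0))
    return lp / _LN10


def call_modified_sites(
    counts: BaseCounts,
    error_rate: float = DEFAULT_SEQUENCING_ERROR,
    alpha: float = 1e-5,
    substitutions: Sequence[str] = ("C>T", "G>A"),
) -> list[EditCall]:
    """One-sided binomial test of excess substitution over sequencing error.

    Per position with a reference base named in ``substitutions`` (C>T and
    G>A by default — the conversions a C>T editor produces on either
    strand), p = P(X >= observed | n = depth, p = error_rate); significant
    iff p < alpha.  Zero-depth positions are skipped with a log message.
    Significance is decided in log10 space so that p-values far below the
    double-precision minimum still compare correctly.
    """
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    wanted = {s.split(">")[0]: s.split(">")[1] for s in substitutions}
    table = counts.table
    refs = table["ref"].to_numpy()
    mat = table[list(BASES)].to_numpy(dtype=float)
    depths = mat.sum(axis=1)
    callable_mask = np.isin(refs, list(wanted)) & (depths > 0)
    n_zero = int((np.isin(refs, list(wanted)) & (depths == 0)).sum())
    if n_zero:
        logger.info("%d zero-depth position(s) skipped", n_zero)
    idx = np.nonzero(callable_mask)[0]
    if idx.size == 0:
        return []
    base_col = {b: i for i, b in enumerate(BASES)}
    positions = [int(table.index[i]) for i in idx]
    subs = [f"{refs[i]}>{wanted[refs[i]]}" for i in idx]
    ks = [float(mat[i, base_col[wanted[refs[i]]]]) for i in idx]
    ns = [float(depths[i]) for i in idx]
    # counts may be fractional after replicate averaging; round for the test
    k_arr = np.rint(np.asarray(ks)).astype(int)
    n_arr = np.rint(np.asarray(ns)).astype(int)
    log10_p = binomial_excess_log10p(k_arr, n_arr, error_rate)
    p = np.power(10.0, np.maximum(log10_p, -323.0))
    p = np.where(log10_p < -323.0, 0.0, p)
    sig = log10_p < math.log10(alpha)
    return [
        EditCall(
            position=pos,
            substitution=sub,
            depth=n,
            rate=k / n if n else 0.0,
            p_value=float(pv),
            log10_p=float(lp),
            significant=bool(s),
        )
        for pos, sub, k, n, pv, lp, s in zip(positions, subs, ks, ns, p, log10_p, sig)
    ]


def calls_to_dataframe(calls: Iterable[EditCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": c.position,
            "substitution": c.substitution,
            "depth": c.depth,
            "rate": c.rate,
            "p_value": c.p_value,
            "log10_p": c.log10_p,
            "significant": c.significant,
        }
        for c in calls
    )
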