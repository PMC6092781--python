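"""Quantify exon skipping from RNA reads by junction-probe classification.

A skipped exon leaves a diagnostic mRNA junction joining its two
neighbouring exons.  Each sequencing unit (a read pair, or a single read)
is classified by exact substring search for two probes built from the
transcript sequence:

* the *skipped* probe spans the exon(n-1)/exon(n+1) junction,
* the *canonical* probe spans the exon(n-1)/exon(n) junction (the 5'
  splice junction of the exon to be skipped).

Units showing the skipped junction count towards the skipped isoform
(taking precedence), units showing only the canonical junction towards the
canonical isoform, and units showing neither are discarded.  Replicate
proportions are pooled with fixed-effect inverse-variance weighting on the
logit scale; per-replicate intervals are exact Clopper-Pearson.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats

from .editquant import WaldResult, wald_two_proportion_test
from .genome import Genome, TranscriptModel, revcomp

logger = logging.getLogger(__name__)

SKIPPED, CANONICAL, DISCARDED = "skipped", "canonical", "discarded"


@dataclass(frozen=True)
class JunctionProbes:
    """Probe pair for one skippable exon; sequences on the transcript strand."""

    skipped_probe: str
    canonical_probe: str
    flank: int  # requested flank length per side (nt); may be truncated

    def __post_init__(self) -> None:
        if self.skipped_probe == self.canonical_probe:
            raise ValueError("skipped and canonical probes are identical; cannot classify")


@dataclass(frozen=True)
class IsoformCounts:
    replicate_id: str
    skipped: int
    canonical: int
    discarded: int

    def __post_init__(self) -> None:
        if min(self.skipped, self.canonical, self.discarded) < 0:
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return self.skipped + self.canonical + self.discarded

    @property
    def informative(self) -> int:
        return self.skipped + self.canonical


@dataclass(frozen=True)
class PooledProportion:
    estimate: float
    ci_low: float
    ci_high: float
    per_replicate: tuple[tuple[float, float, float], ...]  # (proportion, lo, hi)
    pooled_exact_ci: tuple[float, float]  # Clopper-Pearson on summed counts


def exon_sequences(transcript: TranscriptModel, genome: Genome) -> list[str]:
    """Exon sequences on the transcript strand, 5'->3'."""
    return [
        genome.fetch(transcript.contig, s, e, transcript.strand)
        for s, e in transcript.exons
    ]


def make_junction_probes(
    transcript: TranscriptModel,
    skip_exon_index: int,
    genome: Genome,
    flank: int = 20,
) -> JunctionProbes:
    """Build the skipped/canonical probe pair for one inner exon.

    Each probe concatenates ``flank`` nt from each side of the junction;
    flanks are truncated (and logged) when an exon is shorter.
    """
    if not 0 < skip_exon_index < transcript.n_exons - 1:
        raise ValueError(f"exon {skip_exon_index} of {transcript.transcript_id} is not inner")
    seqs = exon_sequences(transcript, genome)
    up, target, down = (
        seqs[skip_exon_index - 1],
        seqs[skip_exon_index],
        seqs[skip_exon_index + 1],
    )
    if min(len(up), len(target), len(down)) < flank:
        logger.info(
            "flank %d truncated to exon length for %s exon %d",
            flank, transcript.transcript_id, skip_exon_index,
        )
    f_up = min(flank, len(up))
    skipped = up[-f_up:] + down[: min(flank, len(down))]
    canonical = up[-f_up:] + target[: min(flank, len(target))]
    return JunctionProbes(skipped_probe=skipped, canonical_probe=canonical, flank=flank)


def _contains(mate: str, probe: str) -> bool:
    return probe in mate or probe in revcomp(mate)


def classify_unit(unit: str | Sequence[str], probes: JunctionProbes) -> str:
    """Classify one unit (read, or mate pair) as skipped/canonical/discarded.

    A probe matches if it occurs in any mate in either orientation; the
    skipped junction takes precedence over the canonical one.
    """
    mates = [unit] if isinstance(unit, str) else list(unit)
    mates = [m.upper() for m in mates if m]
    if not mates:
        raise ValueError("empty unit")
    if any(_contains(m, probes.skipped_probe) for m in mates):
        return SKIPPED
    if any(_contains(m, probes.canonical_probe) for m in mates):
        return CANONICAL
    return DISCARDED


def count_isoforms(
    units: Iterable[str | Sequence[str]],
    probes: JunctionProbes,
    replicate_id: str = "rep1",
) -> IsoformCounts:
    """Tally unit classifications; skipped + canonical + discarded = n units."""
    tally = {SKIPPED: 0, CANONICAL: 0, DISCARDED: 0}
    for unit in units:
        tally[classify_unit(unit, probes)] += 1
    return IsoformCounts(
        replicate_id=replicate_id,
        skipped=tally[SKIPPED],
        canonical=tally[CANONICAL],
        discarded=tally[DISCARDED],
    )


def load_units(path1, path2=None) -> list[tuple[str, ...]]:
    """Read single or paired FASTA/FASTQ into units (mates paired by order)."""

    def _read(path):
        fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]

    first = _read(path1)
    if path2 is None:
        return [(s,) for s in first]
    second = _read(path2)
    if len(first) != len(second):
        raise ValueError("mate files differ in record count")
    return list(zip(first, second))


def clopper_pearson_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact equal-tailed binomial confidence interval (beta-quantile form)."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    alpha = 1 - confidence
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    high = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return low, high


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    return 1 / (1 + math.exp(-x))


def pool_replicates(
    counts: Sequence[IsoformCounts], confidence: float = 0.95
) -> PooledProportion:
    """Fixed-effect inverse-variance pooling of replicate skip proportions.

    Proportions are combined on the logit scale (variance 1/k + 1/(n-k));
    boundary counts get a 0.5 continuity correction.  Per-replicate
    intervals are Clopper-Pearson; the pooled interval comes from the
    inverse-variance model, with a Clopper-Pearson interval on the summed
    counts also reported.
    """
    usable = [c for c in counts if c.informative > 0]
    if not usable:
        raise ValueError("no replicate has informative (skipped+canonical) units")
    if len(usable) < len(counts):
        logger.warning("%d empty replicate(s) dropped from pooling", len(counts) - len(usable))

    per_rep = tuple(
        (c.skipped / c.informative, *clopper_pearson_ci(c.skipped, c.informative, confidence))
        for c in usable
    )
    tot_k = sum(c.skipped for c in usable)
    tot_n = sum(c.informative for c in usable)
    pooled_exact = clopper_pearson_ci(tot_k, tot_n, confidence)

    if len(usable) == 1:
        c = usable[0]
        p = c.skipped / c.informative
        lo, hi = clopper_pearson_ci(c.skipped, c.informative, confidence)
        return PooledProportion(p, lo, hi, per_rep, pooled_exact)

    logits, weights = [], []
    for c in usable:
        k, n = float(c.skipped), float(c.informative)
        if k == 0 or k == n:
            k, n = k + 0.5, n + 1.0
        logits.append(_logit(k / n))
        weights.append(1.0 / (1.0 / k + 1.0 / (n - k)))
    w = np.asarray(weights)
    x = np.asarray(logits)
    pooled_logit = float((w * x).sum() / w.sum())
    se = math.sqrt(1.0 / w.sum())
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    return PooledProportion(
        estimate=_expit(pooled_logit),
        ci_low=_expit(pooled_logit - z * se),
        ci_high=_expit(pooled_logit + z * se),
        per_replicate=per_rep,
        pooled_exact_ci=pooled_exact,
    )


def skip_rate_test(control: IsoformCounts, edited: IsoformCounts) -> WaldResult:
    """Two-tailed Wald test of equal skip proportions (control vs edited)."""
    if control.informative == 0 or edited.informative == 0:
        raise ValueError("both samples need informative units")
    return wald_two_proportion_test(
        control.skipped, control.informative, edited.skipped, edited.informative
    )
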