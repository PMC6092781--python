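# Methods

This note documents the models, conventions and numerical choices behind
`exonskip`, and what the synthetic fixtures do and do not establish.

## Coordinates and acceptor geometry

Internally all intervals are 0-based half-open; GTF I/O is 1-based inclusive
per the GTF standard, and BED exports are 0-based half-open. Exon lists are
ordered 5'→3' in transcript orientation (descending genomic start on the
minus strand).

For an inner exon, the splice-acceptor guanosine is the last intronic base
5' of the exon in transcript orientation: genomic position `exon.start − 1`
on the plus strand, `exon.end` (read as the complement) on the minus strand.
The terminal intronic dinucleotide is recorded verbatim; non-`AG` acceptors
are retained with a warning rather than dropped, since the `AG` rule has
rare exceptions. Acceptors shared by several transcripts can be
deduplicated by genomic position for design (each retained reference still
names its transcript); both behaviours are exposed because annotation sets
routinely contain exons that are internal in one transcript and terminal in
another.

## Guide placement

Protospacer positions are numbered 1-based from the PAM-distal end, so a
target C at position p of an L-mer lies `L − p + 1` bp from the PAM. The
editable C is the antisense complement of the acceptor G, hence the guide
always lies on the strand opposite the transcript:

* transcript `+`: guide on `−`, protospacer `[s, s+L)` with `s = g − L + p`,
  PAM at `[s−k, s)`;
* transcript `−`: guide on `+`, `s = g − p + 1`, PAM at `[s+L, s+L+k)`.

One candidate is emitted per profile position with non-zero efficiency,
subject to the protospacer carrying a C there and the PAM matching.
Candidates are ranked by predicted efficiency, ties broken by smaller
target position then leftmost genomic start (the ranking is a package
convention; nothing downstream depends on it). Genomic `N` bases match no
IUPAC pattern letter, including `N`.

The first exonic base sits at protospacer position `p − 1`; when it is a G
and that position has non-zero efficiency the candidate is flagged as a
potential bystander edit (the editor may convert the exonic C as well).

## Editors and efficiency profiles

Four C>T editors ship as a JSON config: SpCas9-BE3 (NGG, 20-nt
protospacer), SpCas9-VQR-BE3 (NGA, 20 nt), SpCas9-VRER-BE3 (NGCG, 20 nt)
and SaCas9-KKH-BE3 (NNNRRT, 21 nt). Protospacer lengths are the scaffolds'
canonical values. The per-position efficiency profiles are *approximate*
values digitized from published editing-window figures (Kim et al. 2017);
they are data, not code, and are meant to be replaced by users with better
measurements. The SpCas9-BE3 window spans positions 4–9, equivalent to a
12–17 bp C-to-PAM distance. NAG is recorded as a secondary PAM for SpCas9
editors: excluded from design by default (primary PAMs only) but accepted
during off-target scanning, where weaker PAM binding is still a liability.

`build_efficiency_profile` turns replicate measurements into a profile
conservatively: a position reports its replicate mean only when a one-sided
one-sample t-test rejects "mean efficiency ≤ 0" at p < 0.1. Single-replicate
positions cannot be tested and report 0 (logged); a zero-variance positive
constant is accepted as significant.

## Off-target model

Candidate sites are every genomic placement, on either strand, with at most
`max_mismatches` (default 2) protospacer mismatches and a PAM from the scan
set. The scan is vectorised (sliding-window mismatch counting over an
integer-encoded genome) but its contract is set-equality with an exhaustive
brute-force search, which the tests enforce on every fixture.

The per-site score is the experimentally derived single-site scheme of Hsu
et al. 2013, rescaled to 0–100: mismatch positions M contribute
`Π(1 − w_p)`, and for |M| ≥ 2 two attenuation terms,
`1/(((L−1−d̄)/(L−1))·4+1)` (clustered mismatches hurt binding more than
spread-out ones) and `1/|M|²`. A perfect match scores exactly 100. The
20-mer weight vector is the published matrix; the 21-mer vector for
SaCas9-KKH pads one zero at the PAM-distal end, where mismatches carry the
least penalty — a pragmatic extension, since no published 21-mer matrix
exists. Weights live in a JSON config; the tests use a synthetic vector so
scoring-code correctness is independent of the published values. Guides
whose best off-target site (excluding the on-target locus) scores **strictly
above 10** are discarded; a top score of exactly 10.0 survives. Indel
("bulge") off-targets are not modelled.

## Editing quantification

Base counts come from a pileup TSV (contig, 1-based position, ref, A, C, G,
T, N) or from streaming a SAM (aligned pairs only, so deletions and clips
contribute nothing; no index required). Replicates are merged by averaging
per-position base *fractions* and rescaling by mean depth — with equal
depths this equals count averaging; with unequal depths the fraction
average is what "duplicates were averaged" means for reported rates.
Statistical tests on two samples use pooled replicate counts.

The two-sample test is a two-tailed Wald test for equal binomial
proportions. When both sample variances vanish (each proportion 0 or 1) the
statistic is undefined; equal proportions give p = 1 and unequal ones fall
back to a pooled-variance z (logged). Off-target calling uses a one-sided
upper-tail binomial test against the sequencing error rate as background
probability, cutoff 1e-5, applied only to C>T and G>A — the conversions a
C>T editor can produce on either strand; other substitutions are reported
but never called. Deep amplicons push p-values below the smallest double,
so every p is accompanied by a log10 value computed in log space (with a
log-sum-exp fallback where the survival function underflows); significance
is decided on the log scale.

The error-rate estimator defaults to the unweighted mean over control sites
of the non-reference depth fraction, with the pooled-count estimate behind
a flag (the two differ under unequal depths; the unweighted mean is the
primary estimator as it weights sites, not reads). When no control sample
is available the documented platform default of 0.383% is used.

## Skipping quantification

For exon n, two probes are built from transcript-strand sequence with 20-nt
flanks per side (truncated to the exon length when an exon is shorter):
the skipped probe spans the exon(n−1)/exon(n+1) junction, the canonical
probe the exon(n−1)/exon(n) junction. A read unit (single read or mate
pair) is *skipped* if any mate contains the skipped probe in either
orientation, else *canonical* if any mate contains the canonical probe,
else *discarded*; skipped takes precedence in the degenerate case where
both occur. Exact substring matching against both orientations reproduces
the junction logic of a spliced aligner without requiring one; at 20-nt
flanks a probe is effectively unique at fixture scale. Conservation
(skipped + canonical + discarded = units in) is an enforced invariant.

Replicate proportions are pooled by fixed-effect inverse-variance on the
logit scale (variance `1/k + 1/(n−k)`, continuity correction 0.5 at
boundary counts), back-transformed; the pooled CI comes from the
inverse-variance model and a Clopper–Pearson interval on the summed counts
is reported alongside, since either is a defensible summary. A single
replicate reports its own proportion with its exact interval.
Clopper–Pearson intervals use the beta-quantile form and are checked
against direct binomial-CDF inversion.

## Synthetic fixtures

`make_toy_genome` builds one contig per transcript (alternating strands):
intergenic flanks, 3–5 exons of 60–120 bp, introns of 80–200 bp forced to
`GT…AG`. Requested guides are planted by writing a concrete PAM instance at
the placement that puts the acceptor's antisense C at the requested
protospacer position; requested off-target sites are mutated copies of a
planted protospacer written into the intergenic flank with a valid PAM.
After planting, a scrub pass deletes every *accidental* design-range PAM
(for all requested editors and profile positions) by mutating a PAM base,
so the ground-truth manifest is the complete set of designable guides —
the property the oracle-equivalence tests rely on. `N` positions of a
planted PAM are drawn from {A, C} so a planted PAM cannot seed a shifted
accidental match that could not be scrubbed without destroying the plant.

Pileups are multinomial draws per position: the sequencing error rate is
spread uniformly over the three non-reference bases, and the edited
position adds the true edit rate to its designated alternative. Junction
units draw skipped status per unit, sample a fragment guaranteed to span
the junction with a full probe flank in at least one mate, and mix in 10%
junction-free filler units to exercise the discard rule. Defaults are the
regimes the method targets in practice: edit rate 26.38% (6.26–46.61%
tested), error 0.383%, depth 5000, skip fraction 32.46% (15.46% also
tested), 2000 units per replicate, 100-nt reads (junction windows at toy
exon scale; real paired-end reads are longer, which only makes probe
matching easier). One integer seed drives everything; each artifact kind
uses a fixed substream so outputs are byte-reproducible and adding an
artifact never reshuffles the others.

What the fixtures do **not** emulate: alignment artefacts, indels,
position-dependent error profiles, PCR amplification bias between isoforms
of different lengths (a known caveat of junction counting), chromatin
effects on editing, or cryptic splice-acceptor activation — so passing
tests establish correctness of the computations, not biological accuracy
of the predictions.

## Problem sizes

Fixture genomes are a few kb per contig; oracle-equivalence tests run 20
seeded fixtures against brute-force scans, statistical recovery tests use
200 seeded replicates at depth 5000 (edits) and 2 × 2000 units (skipping),
and the null-specificity check simulates 10⁵ sites. These sizes give the
recovery assertions comfortable binomial margins while keeping the whole
suite under a minute of compute on one core.

## Known limitations

* Efficiency profiles are digitized approximations; predicted efficiencies
  rank candidates but are not calibrated probabilities.
* The off-target score is a single-site similarity heuristic; it does not
  aggregate genome-wide risk nor use chromatin accessibility.
* Probe classification requires exact junction sequence; SNVs or sequencing
  errors inside a probe window push reads into the discarded class
  (mismatch-tolerant matching is available but off by default).
* GTF support targets the GENCODE dialect (`transcript_type`/`gene_type`,
  generic `biotype` fallback); full GFF3 is out of scope.
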