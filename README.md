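# exonskip

Design sgRNAs for CRISPR C>T base editors that force **exon skipping** by
disrupting splice acceptors, and quantify the editing and skipping outcomes
from sequencing-style data.

## The problem

Nearly every intron ends in the dinucleotide `AG`; the terminal guanosine of
that splice acceptor is essential for the spliceosome to recognise the
downstream exon. A C>T base editor (a Cas9 nickase fused to a cytidine
deaminase) can deaminate the cytidine on the antisense strand that is
complementary to this guanosine, converting G>A on the sense strand without a
double-strand break. The damaged acceptor is no longer recognised and the exon
is left out of the mature transcript — a permanent, DSB-free route to exon
skipping for inner exons (those that are neither first nor last in their
transcript).

`exonskip` implements the computational workflow around this idea:

1. **Acceptor discovery** — parse a genome (FASTA) and gene models (GTF),
   enumerate inner exons and locate each acceptor G with correct strand
   handling (`exonskip.genome`).
2. **Guide design** — for each base editor (NGG, NGA, NGCG and NNNRRT PAMs
   shipped), enumerate protospacer placements on the antisense strand whose
   editing window covers the target C, attach per-position predicted
   efficiencies, and flag *bystander* edits (an exon whose first base is G
   puts a second editable C inside the window) (`exonskip.design`,
   `exonskip.editors`).
3. **Specificity filtering** — scan the genome for all sites with at most two
   protospacer mismatches and a compatible PAM, score each site on the 0–100
   position-weighted similarity scale (100 = perfect match, Hsu et al. 2013
   weights), and discard guides whose best off-target site scores above 10
   (`exonskip.offtarget`).
4. **Editing quantification** — per-position base counts from pileup tables
   or SAM, replicate averaging, modification rates, a two-tailed Wald test of
   equal binomial proportions against a control, and a one-sided binomial
   test against the sequencing error rate (default 0.383%) at a 1e-5 cutoff
   for off-target calling (`exonskip.editquant`).
5. **Skipping quantification** — classify RNA reads by exact junction-probe
   matching (skipped vs canonical 5' junction, neither = discarded) and pool
   replicate proportions with fixed-effect inverse-variance weighting on the
   logit scale plus exact Clopper–Pearson intervals (`exonskip.skipquant`).
6. **Synthetic fixtures** — seeded toy genomes with planted PAMs, planted
   off-target sites and simulated pileups/junction reads at known rates, so
   the whole pipeline is testable without downloads (`exonskip.simulate`).

## The statistics, briefly

* Editing-efficiency profiles are conservative: a protospacer position gets
  its mean replicate efficiency only when a one-sided one-sample t-test
  rejects "mean ≤ 0" at p < 0.1, else 0.
* Off-target site score for mismatch positions M:
  `100 · Π_{p∈M}(1−w_p) · [((L−1−d̄)/(L−1))·4+1]^{-1} · |M|^{-2}` (the last
  two factors only for ≥2 mismatches), with w the per-position weight vector
  and d̄ the mean pairwise mismatch distance.
* Wald test: `z = (p̂₁−p̂₂)/√(p̂₁(1−p̂₁)/n₁ + p̂₂(1−p̂₂)/n₂)`, two-sided normal p.
* Off-target calls: `p = P(X ≥ k | n = depth, p₀ = error rate)`, significant
  iff p < 1e-5; p-values below double precision are reported as log10 bounds.
* Pooling: inverse-variance fixed-effect on logit(p̂) with a 0.5 continuity
  correction at boundaries; per-replicate CIs are exact Clopper–Pearson.

## Worked example

Generate a seeded toy fixture, design guides, and quantify simulated outcomes:

```console
$ exonskip simulate fixture --seed 11
fixture written to fixture (seed 11)

$ exonskip design fixture/genome.fa fixture/annotation.gtf --editor SpCas9-BE3
3 acceptors scanned; 2 guides designed; 1 kept -> guides.tsv / guides.bed
```

`guides.tsv` holds one row per surviving guide, e.g.

```
editor       protospacer            pam  target_c_position  c_to_pam_distance  predicted_efficiency
SpCas9-BE3   TATGACTAACAGAGTATGAG   AGG  6                  15                 0.43
```

The protospacer carries the target C at position 6 (PAM-distal numbering),
15 bp from the PAM — inside the 12–17 bp geometry the NGG editor requires —
with predicted efficiency 0.43. The second designed guide was removed because
a planted off-target site scored above the cutoff of 10.

```console
$ exonskip quantify-edits fixture/pileup.tsv
error rate 0.003830; 1/25 sites significant -> edit_calls.tsv

$ exonskip quantify-skipping fixture/genome.fa fixture/annotation.gtf \
    --transcript TX1 --exon-index 1 \
    --reads fixture/reads_R1.fastq,fixture/reads_R2.fastq
pooled skip fraction 0.3230 [0.3015, 0.3451] -> skipping.json
```

The one significant site is the acceptor base itself (simulated G>A at
26.38%); the pooled skip fraction recovers the simulated 32.46% within its
95% interval.

The same operations are available as library calls; see the module
docstrings and `docs/methods.md`.

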