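# Methods

## Coordinates and annotation model

All internal coordinates are 0-based, half-open `[start, end)`; GTF I/O
(1-based, closed) converts only at the boundary, and the conversion is
tested to be self-inverse. Only `exon` features define gene structure;
transcript-level features (`mRNA`, `ncRNA`, `pseudogene`) and
`gene_biotype`-style attributes contribute biotype evidence. A gene is
`protein_coding` if any transcript is; unrecognized biotypes become
`other` and, like pseudogenes, are excluded from antisense pairing. Genes
whose transcripts sit on multiple chromosomes or strands are rejected: the
overlap rules below are undefined for them. "First exon" and "last exon"
are defined per transcript in transcription order (on the minus strand the
first exon is the highest-coordinate one); at gene level the first-exon
set is the union over transcripts, the most permissive reading
(`exon_terminal_scope="union"`, with `"longest_transcript"` as the
alternative).

## Antisense pairs and configurations

A sense/antisense pair is one lncRNA and one coding gene on opposite
strands with at least 1 exonic nucleotide of overlap. Two overlap dialects
exist because annotations differ in whether an intronic antisense gene
counts as overlapping:

* `exon_vs_span` (default): ≥ 1 exonic base of either gene inside the
  other gene's genomic span. This captures the biologically central case
  of a lncRNA inside a host intron.
* `exon_vs_exon`: ≥ 1 base shared by the two exon unions (strict exonic
  complementarity).

Configuration labels are assigned with the precedence
**internal > external > head_to_head > tail_to_tail > other_overlap**, and
containment is span-based — an intronic lncRNA is internal to its host
even without exon-exon contact. Head-to-head requires both a geometric
condition (the two 5′ ends face each other across the overlap) and a
first-exon contact (a 5′-terminal exon of one gene overlapping any exon of
the other); tail-to-tail is the 3′ analogue. When a pair satisfies both
terminal contacts without containment, the 5′ reading wins — an arbitrary
but frozen tie-break. Mid-body overlaps that match no named class are kept
under the explicit `other_overlap` label rather than forced into a named
category or silently dropped. Finally, every pair inside a connected
component of the gene-overlap graph with more than 2 genes is relabelled
`complex` (components via networkx; a deliberately independent per-base
brute-force oracle re-derives pairs, labels and components for
verification on small genomes).

The defaults (`exon_vs_span`, terminal scope `union`) are the package's
frozen reference mode; both are exposed as switches because annotated
genomes differ in how intron-hosted antisense genes are represented, and
a census on a real annotation is sensitive to this dialect.

## Expression filter and screen statistic

A gene counts as expressed when **all replicates of at least one tissue**
reach the TPM threshold (default 0.5 TPM, inclusive); a pair survives when
both members pass, not necessarily in the same tissue. Only pairs whose
coding gene has ≥ 2 annotated isoforms are screened — a NAT can only
modulate isoform usage where there is a choice of isoforms.

For each (pair, distinct exon of the coding gene) and each sample, the
exon inclusion ratio is the mean per-base coverage over the exon divided
by the mean over the gene region. The gene denominator is the whole
genomic span by default (`gene_region_mode="span"`, matching a span query
of a coverage summarizer); `"exon_union"` is offered because intron-heavy
genes dilute a span denominator — for such genes the span-mode ratio of a
constitutive exon itself shifts when isoform usage changes the exonic
total, a sensitivity worth knowing when interpreting positive correlations
of constitutive exons. Ratios are undefined (NaN, flagged via `n_valid`)
exactly where the gene denominator is zero; undefined values are dropped
pairwise, never imputed.

The selection statistic is the Pearson correlation r between per-sample
exon ratios and the antisense gene's TPM, over all individual samples
(tissue × replicate; a `collapse_replicates` switch averages within tissue
first). Antisense TPM enters raw; a `log1p_nat` switch is provided.
r is undefined with fewer than `min_valid=3` defined samples or when
either vector is constant. An exon is selected when `sd > 0.1` **and**
`|r| > 0.7`, both strict; sd is the sample standard deviation (ddof = 1)
of the defined ratios. Output is ordered by |r| descending, then sd, with
a deterministic (gene, exon-start) tie-break. Undefined sd or r can never
be selected.

Coverage tracks are unstranded totals unless per-strand tracks are
supplied (samples table columns `coverage_file_plus`/`coverage_file_minus`),
in which case each gene reads its own strand. With unstranded tracks an
intron-hosted NAT contributes to its host's span denominator, which can
itself induce correlation; stranded tracks avoid this confound and are
what the generator emits by default.

## The synthetic study

The generator emulates a stranded RNA-seq design over three larval
imaginal-disc tissues (wing, leg, eye) with two replicates each, and a
locus family modelled on *bs/bsAS*:

* a coding gene with two TSSs and three isoforms — short two-exon isoform
  B (TSS1), long isoforms C (TSS1) and A (TSS2) — sharing a constitutive
  MADS-box-like exon, with a long-isoform-specific 3′ exon downstream of a
  long intron that hosts the antisense lncRNA (an `internal` pair);
* antisense TPM levels per tissue of 30 (wing), 2 (leg), 0.05 (eye) —
  high in wing, essentially silent in eye;
* coding-gene totals of 60/40/40 TPM with the long-isoform A/C split fixed
  at 0.5 so that exon-level truth stays interpretable;
* a **coupling law** `f = clip(f0 + slope · nat_tpm, 0, 1)` for the
  long-isoform fraction, defaults `f0 = 0.8`, `slope = −0.025` per TPM.
  This is a deliberately simple monotone stand-in for transcriptional
  interference (e.g. polymerase collision); the mechanism itself is not
  modelled. At the wing antisense level it drives the long fraction from
  0.8 to ≈ 0.05;
* noise: multiplicative lognormal with unit mean throughout — CV 0.2 per
  replicate on TPM levels, CV 0.05 per exon per sample on coverage; mean
  per-base coverage is `read_depth_scale = 10` per TPM of each isoform
  covering the base;
* controls: a second internal pair with coupling slope 0 (its antisense
  RNA varies across tissues but isoform usage is fixed — the statistical
  false-positive control) and an antisense-free two-isoform gene (which
  forms no pair and must never appear in the candidate table).

Gene-level TPM is the exact sum of the simulated isoform TPMs, and all
randomness flows from a single seed (identical config + seed reproduces
outputs byte-for-byte).

Because the inclusion ratio is a smooth monotone — but not affine —
function of the antisense TPM (the denominator also moves with isoform
usage), the noise-free correlation of a long-specific exon is close to,
not exactly, −1; tests assert r < −0.95 in the noiseless limit and
selection with negative r under the default noise.

What the generator does **not** emulate: read-level sampling (no FASTQ,
no junction reads), mappability and GC effects, transcript-assembly or
quantification error in the TPM tables, partially overlapping exon
variants, or the collision mechanism itself. Passing the recovery test
therefore shows that the statistic recognises a planted monotone coupling
at realistic noise, not that real tissues satisfy the coupling law.

## Verification problem sizes

The brute-force oracle comparison uses 200 seeded random genomes of ≤ 50
genes over ≈ 20 kb (per-base boolean masks, quadratic pair loops); the
planted-recovery check uses 50 seeded studies (6 samples each), requiring
≥ 90 % recovery of planted long-isoform-specific exons and zero selected
control exons; a planted census genome (13 loci, 15 pairs) is classified
end-to-end through GTF. These sizes keep the default suite and the
acceptance script in the seconds range while giving the Monte-Carlo checks
enough trials to be meaningful.

## Known limitations

* The screen is correlational with fixed thresholds; it produces ranked
  candidates, not significance calls, and no multiple-testing control.
* Distinct exons are distinct `(start, end)` pairs; alternative 5′/3′ ends
  of the *same* exonic region are separate exons, and partially
  overlapping variants are each measured against the shared coverage.
* A census on a real genome annotation depends on the overlap dialect of
  that annotation; the shipped defaults are a documented choice, and both
  dialect switches should be tried when reproducing published pair counts.
* Percentages in the census are rounded to whole percent; counts are
  exact.
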