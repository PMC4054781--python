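# Methods

`ocmeth` re-implements, as a tested and reusable pipeline, the integrative
methylome analysis used to characterize monocyte-to-osteoclast (MO → OC)
differentiation: paired differential-methylation calling on bead-array beta
values, maxgap clustering of differential CpGs into regions, integration
with a 0/5/20-day expression time course, transcription-factor motif
enrichment in CpG-centered windows, ChIP-seq peak overlap, and the qPCR
quantitation rules for 5-hydroxymethylcytosine (5hmC), relative expression,
and ChIP percent-input.  A synthetic-data generator with recorded ground
truth makes every stage testable without external downloads.

## Differential methylation

A beta value is the methylated-probe intensity over total intensity, a
methylation proportion in [0, 1]; the M-value is `log2(beta / (1 - beta))`,
the variance-stabilized scale on which all statistics run.  Betas are
clamped to `[1e-3, 1 - 1e-3]` before the logit, bounding |M| near 10.

The DMP workflow is: M transform → quantile normalization → IQR variance
filter (keep probes whose M-value IQR is at or above the 0.50 quantile of
all IQRs, linear-interpolation quantiles, ties kept) → empirical-Bayes
moderated paired t.  Quantile normalization maps each column's sorted
values onto the row-wise mean of all sorted columns; tied values within a
column receive the mean of the reference values at their tied ranks.
Missing values are rejected, not imputed.

For donor-paired samples the per-probe differences `d_i = M(OC_i) - M(MO_i)`
give a mean and a sample variance `s^2` with `d = n_pairs - 1` residual df.
The variance prior `(d0, s0^2)` is moment-matched on `log s^2` (digamma /
trigamma matching with a Newton trigamma inverse); when the spread of
`log s^2` is no larger than chi-square sampling noise, `d0 = inf` and the
moderated t is referred to a normal.  The posterior variance is
`(d0 s0^2 + d s^2) / (d0 + d)` and the moderated t has `d + d0` df.  Probes
with `s^2 = 0` are excluded from hyperparameter fitting but still shrunk
(the classical t would be undefined; the moderated t is finite).  Passing
`prior_df=0` disables shrinkage, recovering the classical paired t — a
limiting identity the tests exploit.

A probe is called differentially methylated when the fold change of
group-mean betas (OC over MO) satisfies `FC >= 2` (hypermethylated) or
`FC <= 0.5` (hypomethylated), with raw `p <= 0.01` and Benjamini–Hochberg
`q <= 0.05`.  Fold change is computed on the beta scale (the interpretable
0–1 proportion, where ratio thresholds are meaningful) from the normalized
M-values mapped back through the logistic; whether the original analysis
used beta or M ratios is not documented, so a flag switches the inclusive
boundary comparison to strict.

Probes are annotated to one region category with promoter precedence:
promoter = TSS1500/TSS200/5'UTR/first exon, then gene body, then 3'UTR;
probes without gene annotation are intergenic.  A gene counts as hypo- or
hypermethylated when at least one of its probes is called in that
direction (a gene can appear in both sets).  A generic Fisher
over-representation test (hypergeometric upper tail, BH-corrected) is
provided for user-supplied gene-set annotations.

## DMR clustering

Within each (chromosome, direction) stratum, called probes are sorted by
position and chained while successive gaps are at most `maxgap` (500 bp);
a gap exactly equal to `maxgap` still joins.  Hypo- and hypermethylated
probes never merge, and singleton clusters are reported.  Clusters with at
least `min_cpgs` members (default report threshold 10) are highlighted as
coordinated regions.  No smoothing or region-level statistic is computed;
the probe-level p-values carry the evidence.

## Expression integration

Expression enters as background-corrected log2 intensities (the RMA
convolution model is out of scope; synthetic or user-supplied values stand
in).  Probe sets are summarized per gene with Tukey median polish
(alternating row/column median sweeps until the total absolute change of a
sweep is < 1e-6, at most 10 sweeps; the per-sample gene value is the
overall effect plus the column effect).  The day-0 versus day-20 contrast
is the default.  Differential expression uses the same quantile
normalization, IQR filter, and variance-shrinkage machinery (unpaired,
pooled variance) with strict fold-change thresholds (`FC > 2` or `< 0.5`)
and `p < 0.01`, `q < 0.05`.

Gene identifiers are matched by case-folded symbol.  Joint classes
(hypo+up, hypo+down, hyper+up, hyper+down, methylation-only,
expression-only) are set intersections.  The methylation–expression
relationship is summarized as the OLS slope of expression log2FC on
delta-beta, with one point per differentially methylated CpG, grouped by
the probe's derived region category (the original figure uses a finer
five-way split; per-CpG points with delta-beta were chosen because the
exact construction is not documented).  Categories with fewer than three
points are skipped with a logged notice.

## Motif enrichment

PFMs are read from TRANSFAC flat files (matrices themselves are licensed
and therefore user-supplied; the built-in synthetic set encodes consensus
sequences of osteoclastogenesis-relevant factors — an ETS/PU.1-like core
plus AP-1, NF-kB, C/EBP and MEF2-like decoys).  A PFM becomes a PWM by
`log2(((count + 0.25) / (total + 1)) / background)` against a uniform (or
sequence-estimated) background.

Score thresholds are exact: scores are floored onto a 0.001-bit grid and
the full distribution of the total score of a random background L-mer is
computed by dynamic programming (convolution over positions); the
threshold is the smallest grid score whose survival probability is at or
below the requested p-value (0.00002 for the hypo/hyper cohorts, 0.00001
for the background cohort, matching the asymmetric cutoffs of the original
analysis).  If no score attains the cutoff the maximum score is returned
with a flag.  For motifs of length <= 8 the DP threshold equals exhaustive
4^L enumeration, which the tests verify.

Windows are the 500-bp, 0-based half-open intervals centered on each CpG
(`[pos-1-250, pos-1+250)`), truncated at contig ends; cohorts are the
hypo-called, hyper-called, and all remaining ("other") probes, the last
serving as the enrichment background.  Both strands are scanned at every
offset; any placement covering an N scores -inf; a window is a hit when at
least one placement reaches the threshold (enrichment is over windows, not
match counts).  Per motif, the 2x2 cohort-by-hit table is tested with a
two-tailed Fisher exact test — hypergeometric summation over tables with
probability at most that observed, computed with exact integer weights —
BH-corrected across motifs, significant at `q <= 0.25`.  Odds ratios use
the Haldane–Anscombe 0.5 correction when a cell is zero.

## ChIP-seq overlap

Peaks are 3–6 column BED (0-based half-open), validated and sorted on
read.  A CpG is peak-positive when its 500-bp window — the same
construction used for motif scanning, by shared code — intersects at least
one peak by >= 1 bp (bedtools-intersect default semantics).  Fractions are
reported per cohort and per stratum (promoter versus distal, where distal
= gene body + 3'UTR + intergenic).  Overlap between peak-supported and
motif-predicted target sets is reported as Venn counts with a Jaccard
percentage (intersection over union); the denominator is switchable to
either set because the original figure does not define it.

## qPCR quantitation

Relative quantity is `efficiency^(Cq_ref - Cq_target)` (efficiency default
2.0, i.e. 100%, exposed per assay because amplification efficiencies are
rarely reported); replicates are always averaged on the linear quantity
scale, never on the Cq scale.  The glucosyltransferase-protection 5hmC
assay glucosylates 5hmC so it resists MspI cleavage at CCGG; the percent
5hmC is `100 * (GT/input - noGT/input)`, where the untreated (no-GT) arm
defines 0%.  Negative differences — expected under noise near 0% — clamp
to 0 with a warning.  ChIP percent-input is
`100 * input_fraction * efficiency^(Cq_input - Cq_bound)`, with optional
IgG-background subtraction floored at 0.  Timepoint groups are compared
with a two-sided Welch t-test and the conventional star coding
(*/**/*** at p < 0.05/0.01/0.001).

## Synthetic data: what it emulates and what it does not

The generator is a pure function of (config, seed) — identical inputs give
bit-identical outputs — and its defaults are the study conditions used
throughout the tests:

- **Methylation**: 20,000 probes, 3 donor pairs; noise is logit-normal
  (Gaussian on the M scale, SD 0.3 — the arrays' true noise magnitude is
  not documented, so this is a calibration choice); a donor random
  intercept (SD 0.5) shared by the MO and OC sample of a donor makes the
  paired test strictly more powerful than an unpaired one.  2.5% of probes
  are planted hypo- and 2.5% hypermethylated with a +-2 logit shift
  (delta-beta ~0.38 from beta 0.5), sized so three pairs give high but
  imperfect power.  Planted hypo probes start mostly methylated (baseline
  logit N(0.8, 0.4)) and hyper probes mostly unmethylated (N(-1.5, 0.4)),
  keeping every planted label reachable by the fold-change definition;
  null baselines come from a bimodal mixture (logit +-2.5, SD 0.8).
  80% of probes sit > 1 kb apart; 20% come in bursts of 3–12 probes within
  500 bp so DMR clustering has non-trivial truth.  Planting is block-wise,
  so genes are direction-consistent and some planted probes cluster.
- **Expression**: 0/5/20-day time course, 3 replicates per timepoint,
  log2 noise SD 0.3.  A methylation-labeled gene changes concordantly
  (hypo→up, hyper→down) with probability `de_coupling` (default 0.62,
  echoing the observed 62% concordance); otherwise, and for all unlabeled
  genes, labels come from a 2% background rate per direction — so at
  `de_coupling = 0` expression labels are independent of methylation
  labels.  Planted genes realize 95% of their total log2 change (magnitude
  uniform on 1.5–3.5) by day 5, emulating the early transcriptional
  response.  `body_coupling_factor` (default 1, i.e. uniform coupling) can
  down-weight coupling for genes without a promoter-region planted probe,
  which the directional slope test uses.
- **Windows**: i.i.d. bases at 50% GC with a PFM-sampled motif instance
  embedded at a random offset/strand in 50% of foreground and 5% of
  background windows.
- **Peaks**: each selected CpG (25% of planted, 5% of other probes —
  scaled to the observed promoter-overlap range) receives one peak
  guaranteed to intersect its window.  Because windows of burst probes
  overlap each other, realized per-window overlap fractions exceed the
  per-probe planting rates; truth flags record the planting exactly.
- **qPCR**: Cq values are back-computed from target trajectories at 100%
  efficiency plus Gaussian Cq noise (SD 0.15); the default 5hmC truth is a
  transient rise-then-fall at rapidly demethylating regions, one region
  primed high, and one flat control.  Zero noise makes quantitation an
  exact inversion.

The generator does **not** emulate: two-channel intensities or IDAT files,
bisulfite conversion chemistry, probe cross-reactivity or SNP artifacts,
spatial chip effects, read-level ChIP-seq data, or amplification-curve
shapes.  Passing tests therefore demonstrate the correctness of the
statistical machinery and of truth recovery under the stated noise model —
not robustness to the artifacts of real arrays.

## Numerical choices and edge cases

- Beta clamp 1e-3 before the logit; generated betas clipped strictly
  inside (0, 1).
- Quantile cutoffs and probe IQRs use linear-interpolation quantiles;
  the IQR comparison is inclusive, so a degenerate all-equal input keeps
  every probe.
- Trigamma inverse by Newton iteration (relative step < 1e-10, 50
  iterations max), with asymptotic shortcuts for extreme arguments.
- PWM grid granularity 0.001 bits, floor rounding; the scanner compares
  discretized placement scores against the discretized threshold, so scan
  hits are exactly consistent with the DP p-values.  With a uniform
  background all DP masses are dyadic rationals and exact in binary
  floating point.
- Fisher two-tailed inclusion uses exact integer weight comparison (no
  floating-point tie tolerance).
- Duplicate (probe, position) rows are an error in DMR clustering;
  mixed-direction or cross-chromosome probes never merge.
- A window shorter than the motif is a miss, not an error; an unattainable
  score cutoff returns the maximum score with a flag, not an exception.
- All randomness flows from a single config seed through per-stage derived
  seeds; the CLI writes sha256 hashes of every output so a rerun under the
  same seed reproduces every hash (no timestamps inside hashed outputs).

## Problem sizes used by the tests and acceptance script

DMP recovery runs 5 seeds at the full default size (20,000 probes x 3
pairs, 500+500 planted); the null control runs 20 seeds at the same size;
motif recovery runs 20 seeds at 200 foreground / 2,000 background windows;
Fisher exactness enumerates every 2x2 table with all margins <= 30; the
end-to-end check is one full default run plus a rerun for hash equality.
These sizes were chosen to give stable Monte-Carlo estimates at desk
scale.

## Known limitations

- The color-balance (two-channel) normalization step of real 450K
  pre-processing needs raw intensities and is out of scope; absolute call
  counts on real data would shift accordingly.
- Only the 500-bp maxgap rule is implemented for region detection; the
  wider multi-scale window scan mentioned alongside it has no documented
  algorithm.
- The enrichment background is the full "other" cohort; the original
  analysis' reported foreground subset sizes are not fully documented, so
  cohort choice is a parameter.
- Whether fold-change thresholds were originally applied to beta or M
  ratios is unknown; beta ratios are the default here.
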