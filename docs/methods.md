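# Methods

chromkit implements, as reusable library code, the bespoke computational
procedures behind a class of regulatory-genomics studies: consensus
filtering of replicate ChIP-seq peak calls, enrichment testing against a
matched-size random-fragment null, scanning for putative G-quadruplex
sequences (PQS), spike-in (ChIP-Rx) coverage normalization,
expression-stratified metagene profiling, and a single-cell analysis that
detects a stochastically silenced cell subpopulation through relative locus
activity.  All stages run on synthetic data with planted ground truth, so
every statistical property is checkable end to end.

## Coordinate model

All coordinates are 0-based half-open (the BED convention), everywhere.
Overlap means at least one shared base; abutting intervals do not overlap.
Chromosome names are compared by exact string match.  The TSS of a
minus-strand gene is its `end - 1` coordinate; promoter windows
(`TSS - up, TSS + down`), default 1000/500 bp, are oriented by strand.
Peak location labels use the precedence promoter > gene body > intergenic.

## Consensus peak filtering

Per-sample peak calls are pooled and chained into connected components
(>= 1 bp overlap links).  A component is retained iff it contains peaks
from at least `min_samples` distinct samples (default 3) and, when
antibody agreement is required, from at least two distinct antibody
labels.  Retained components overlapping a blacklist by >= 1 bp are
removed, as are components whose mean background (input / gDNA) signal
exceeds a threshold; a helper computes the default threshold as mean + 3
SD over random genomic bins.  The reported footprint is the component
union, which makes the output invariant to sample and peak order.

Note one subtlety of component-level support: a chain of k staircased
peaks from k samples counts as k-fold supported even though no single base
is covered k deep.  The tests therefore validate footprints and support
against an independent base-resolution component reconstruction rather
than a per-base depth rule.

## Matched random-fragment enrichment

The null for every overlap claim: draw exactly |observed| fragments whose
length multiset equals the observed one, each placed uniformly over all
genome positions where it fits entirely outside an exclusion set (the
blacklist by default).  Chromosomes are implicitly weighted by their count
of eligible placements.  The observed and null overlap counts against a
feature form a 2x2 table.

`fisher_exact` is implemented from first principles so its conventions are
pinned:

- the two-sided p-value sums central hypergeometric probabilities of all
  tables with the observed margins whose probability is <= that of the
  observed table, with a relative tie tolerance of 1e-7;
- the odds ratio is the conditional maximum-likelihood estimate (CMLE) of
  the noncentral hypergeometric odds parameter — the value at which the
  conditional expectation of the top-left cell equals its observed value,
  solved by Brent's method on the log-odds scale (0 or +inf when the
  observed cell sits on the support boundary; undefined when a margin is
  zero).  Because the conditional likelihood is an exponential family in
  log-psi, the stationary point is the global maximum.
- the raw cross-product odds ratio is reported alongside.

scipy's `fisher_exact` and `odds_ratio(kind="conditional")` are used as
independent cross-checks in the test suite, never as the implementation.
One null draw per test is the default (single reported odds ratios);
`n_draws > 1` additionally yields an empirical permutation p-value.

`uniform_overlap_probability` enumerates, exactly, the fraction of
eligible placements of each fragment length that overlap a merged feature
footprint.  It supplies the analytic expected odds ratio for the
planted-enrichment recovery experiments.

Gene-set association uses windows: a gene "has a peak" iff a peak overlaps
its body extended by `window` bp on both sides (window = 0 means
intragenic), and the 2x2 table crosses set membership with peak presence;
counts are monotone non-decreasing in the window.

## PQS scanning

The motif is the canonical quadparser rule: four runs of >= 3 guanines
separated by loops of 1-7 nt, plus the C-strand mirror; all four numbers
are configurable.  Which exact caller produced any given published hit set
is generally not recoverable, so this configurable rule is a documented
standard, not a claim about any specific tool's output.  Matching is
leftmost-greedy and maximal per strand with the exact backtracking
semantics of a greedy regular expression, which the tests verify
span-for-span against an independent `re`-based oracle.  `N` and
soft-masked lowercase bases never match (a flag lifts the lowercase rule).
Overlap statistics use the merged PQS footprint so nested hits count a
peak once.

## Coverage normalization and metagene profiles

Per-reads scaling multiplies each bin by `denominator / mapped_reads`
(default 1e8, i.e. per 100 million reads); which read count to use (library
total or reads under peaks) is the caller's choice of argument.  A track
carries its normalization provenance and refuses double normalization.

ChIP-Rx scaling uses the reference-adjusted factor

    gamma = (s_input / h_input) / (s_chip / h_chip) * (1e8 / h_chip)

with `h`/`s` the mapped read counts of the target and spike-in species in
the ChIP and input libraries.  The first term corrects the ChIP
spike:target read ratio by the input ratio (cancelling IP-independent
composition), the second removes sequencing depth, so samples prepared at
the same true spike:target cell ratio become quantitatively comparable.

Metagene profiles average a binned track over genes on a common 5'->3'
axis, TSS-centered or with the body length-scaled by linear interpolation
to `body_bins` points (default 100, 2 kb flanks, 50 bp bins).
Minus-strand genes are coordinate-reversed.  Genes truncated by chromosome
ends, or shorter than `body_bins` bases in scaled mode, are dropped and
counted.  Expression strata either cross detection status in two cell
types (expressed in both / A only / B only / repressed) or split detected
genes into equal-count quantile bins, ties broken by gene id for a
deterministic partition.

## Single-cell relative activity

QC follows the standard droplet workflows: accessibility cells need
`passed_filters > 500` fragments (strict) and are subsampled to exactly
4,000 per sample; RNA cells with mitochondrial fraction above 7.5% or a
detected-gene count outside [800, 4000] are excluded (boundary values are
kept) before subsampling to 4,400.  Subsampling is seeded per sample and
invariant to input row order.

Gene activity counts fragments overlapping the gene body extended 2,000 bp
upstream (strand-aware); one fragment counts once per gene.  Activities
are depth-normalized to counts per 10,000; RNA uses
`ln(1 + 1e4 * c / total)` with `sumHBA` computed by summing the HBA1 and
HBA2 counts before the transform (summing on the count scale keeps the
quantity a single locus-level expression).

The silenced subpopulation is defined by explicit thresholds rather than a
visual embedding gate: a cell is *anchor-high* when its HBB-like anchor
activity exceeds the control group's 75th percentile (accessibility) or a
fixed log-normalized expression of 8 (RNA); it is *flagged* when it is
anchor-high and its mean target:anchor ratio falls below the 25th
percentile of the control anchor-high cells.  Ratios are computed on the
linear normalized scale, so a multiplicative silencing of the target
rates maps proportionally onto the ratio (log-scale levels are kept for
thresholds and display); a cell with zero anchor activity has an undefined
ratio and is excluded from ratio summaries.  The flagged set's
case/control composition is tested with the exact test above; per-sample
tables against the pooled controls are also available.

Because the ratio cutoff is a control quantile, roughly a quarter of the
anchor-high control cells are flagged *by construction* — the gate is a
relative one, exactly as a visual gate on a mixed embedding contains
control cells.  Recovery of planted silenced cells is therefore scored as
sensitivity over all planted cells and precision among flagged cells of
the case sample, where the truth lives; both definitions are computed and
reported by the acceptance script.

## Synthetic data: what it emulates, and what it does not

The generator is deterministic under its seed, with independent child
streams per product, and every planted object is recorded.

- **Genome** (default 2 x 3.5 Mb): i.i.d. uniform nucleotides with planted
  PQS motifs (three-G runs, A/C/T loops, padded so the scanner must
  recover each one), non-overlapping genes separated by >= 1.5 kb, CpG
  islands and blacklist regions avoiding genes and each other.
- **Peak replicates**: a latent set of 2,000 peaks (200-400 bp), half
  centred on distinct TSS, the rest uniform outside the blacklist and
  mutually separated so components never chain; each of 6 samples observes
  each latent peak independently with probability 0.9 and adds ~Poisson(20)
  spurious peaks placed away from the latent footprint; two antibodies
  assigned round-robin.  A separate generator places the background peaks
  independently (mutual overlap allowed) for enrichment-recovery
  experiments, so the background TSS-overlap probability is exactly the
  uniform placement probability that `uniform_overlap_probability`
  computes.
- **ChIP-Rx pair**: identical binding biology (5-fold enrichment in
  TSS windows) sequenced at 5M and 15M reads, spike-in cells at 1:4 with a
  fixed capture factor; read counts and binned Poisson coverage only — no
  read-level simulation.
- **Single cell**: per-cell depths lognormal (median ~5,000 fragments,
  typical of droplet accessibility assays); a per-cell maturity rank
  drives globin-locus rates (anchor fraction 0.2% -> 5% of fragments),
  emulating rising globin accessibility through erythroid differentiation;
  HBA-like and HBM-like rates are fixed multiples of the anchor.  In the
  case sample a fraction f_s (default 0.2) of cells is silenced — HBA/HBM
  rates multiplied by e (default 0.2), anchor untouched.  Silencing
  probability is a logistic ramp in maturity rank (softness tau = 0.02)
  whose midpoint is solved so the expected silenced fraction equals f_s:
  the design intent is that silencing is concentrated in the late,
  anchor-high cells where the relative-activity readout is defined.  A
  strictly rank-proportional probability was rejected because it would
  place most silenced cells outside the anchor-high gate, making them
  undetectable by any relative-activity method.  The RNA modality mirrors
  the design with HBA1+HBA2 proportional to HBB (ratio mu = 1) outside
  silenced cells, plus mitochondrial-fraction and detected-gene metadata
  for QC.  Counts are Poisson; an overdispersion knob is deliberately
  absent — the analyses compare groups of thousands of cells and rank-based
  gates, which are insensitive to modest overdispersion, but heavy-tailed
  technical noise, doublets, batch effects and cell-cycle structure of
  real droplet data are *not* emulated.  Passing tests demonstrate the
  statistics behave as designed under the stated model, not that the
  thresholds transfer untouched to any particular real dataset.

## Numerical choices

- Exact-test ties: relative tolerance 1e-7 on the probability-mass
  ordering, pinned so oracle equality is well defined.
- CMLE: Brent root-finding to |E[X] - a| ~ 1e-12 on the log-odds scale; the
  batched per-margin path uses a safeguarded Newton iteration with the
  same stationarity target and boundary conventions.
- Placement: rejection sampling for mutually spaced intervals (error when
  a feature cannot be placed within 500 proposals); exact cumulative
  eligible-placement inversion for uniform fragments.
- Metagene body interpolation: `np.interp` on per-bp bin values; the
  mirrored evaluation order makes strand-flipped profiles equal to
  floating-point rounding (TSS-centered profiles are bitwise equal).
- Quantile gates use the empirical quantile of the control group; ties in
  depth ranks are broken by array order, deterministically.

## Problem sizes in the validation scripts

The acceptance script validates the exact test on every 2x2 table with
total <= 40 (~138k tables), type-I error on 400 null-vs-null repetitions
of 500 fragments, enrichment recovery on 30 seeds of 2,000 peaks,
consensus retention on 2,000 latent peaks x 6 replicates, the scanner on
200 random 10-kb sequences plus the full planted genome, and the
single-cell gate on 50 power seeds, 50 null seeds and 20 recovery seeds at
4,000 cells per sample.  The test suite runs the larger versions (tables
<= 60, 1,000 scanner sequences, 1,000 type-I repetitions, 100 seeds per
single-cell condition).

## Known limitations

- The consensus rule is component-level; no IDR-style reproducibility
  score and no raw peak calling.
- The null is uniform within allowed space: no GC, mappability or
  chromatin-state matching.
- The PQS rule is the canonical four-run pattern; bulged or two-quartet
  quadruplexes and stability scores are out of scope.
- bigWig is not read or written; bedGraph text stands in.
- The single-cell gate assumes a single anchor locus and a monotone
  maturity axis; trajectory inference, doublet handling and cluster-level
  marker testing are out of scope.
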