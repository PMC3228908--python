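# Methods

This note documents the models, defaults and numerical choices behind
aeiscope, and what the synthetic-data generators do and do not emulate.

## Read processing

Reads are single-end: a 5-bp sample index followed by an amplicon insert in
either orientation.  All coordinates are 0-based.

**Demultiplexing.** Index 5-mers satisfy base1 = base5 (redundancy).  Two
modes: `exact` (default) accepts only perfect prefix matches; `correct`
additionally accepts a unique index matching ≥4 of 5 positions, provided an
interior (positions 2–4) mismatch leaves the read's own base1 = base5
intact — a broken redundancy with an interior mismatch implies two errors
and is untrusted.  Score ties are never resolved arbitrarily (unassigned).
Guarantees, by construction and tested exhaustively: a prefix with one
substitution is either corrected to its true sample or dropped, never
cross-assigned.  A coordinated double substitution at the two redundant
positions can defeat any 5-bp redundant design; at 1% per-base error this
occurs at the ~1e-4/read level.  The redundancy constraint caps the
index-space: at most ~16 indices exist at pairwise Hamming distance 3, so
52-index sets are packed at distance 2 and rely on `exact` mode or accept
the small ambiguity loss in `correct` mode.

**Matching.** Amplicons are short (66–100 bp) and indels are not modeled,
so reads are matched by ungapped identity over the aligned overlap against
each amplicon and its reverse complement (the in-repo replacement for an
external aligner; deterministic and oracle-testable against exhaustive
Hamming search).  Defaults: `min_identity = 0.9` over the overlap,
`min_read_length = 30` (the only length gate — base qualities are parsed
but not used).  A best-identity tie across distinct genes is ambiguous and
becomes `no_match`.

**Allele extraction.** The matched read is orientation-normalized onto
amplicon coordinates.  Reads physically begin at one amplicon end, so the
normalized sequence is anchored at the amplicon start or end, whichever
aligns better; this makes extraction invariant under reverse-complementing
a read with flipped orientation.  The mSNP base is reported as M/m only if
the up- and downstream flanks (20 bp each, truncated at read/amplicon ends)
each contain ≤2 mismatches; an uncovered mSNP is `missing`, anything else
`neither`.  Triage conserves reads exactly:
`total = failed_match + missing_msnp_base + usable`, with `neither` counted
under the missing-mSNP class; `single_allele_only` flags usable
(sample, gene) records where a recorded heterozygote yielded one allele — a
genotype-discordance signal, not a discard class.

## AEI ratios and bias correction

The AEI ratio is numerator-allele count / denominator-allele count (the
numerator allele is a per-gene property of the reference table; no global
convention).  log2 makes positive and negative imbalances symmetric.
Records with a zero allele count are excluded with a reason rather than
pseudocounted (a `+0.5` pseudocount option exists but is off by default —
ratios are simply not formed from zero counts).

PCR amplifies the two alleles with gene-specific efficiency (biases beyond
1.5-fold occur).  Since gDNA from a heterozygote carries the alleles
exactly 1:1, the per-gene correction factor is the inverse of the mean
uncorrected gDNA linear ratio; it multiplies both gDNA and cDNA ratios, and
afterwards the per-gene arithmetic mean of corrected gDNA ratios is 1 to
machine precision.  "Mean" is arithmetic by default (the natural reading of
an averaged linear ratio); a geometric option is provided as the
log2-symmetric alternative.  No outlier exclusion is performed before
averaging.  Double application is refused via the `corrected` flag.

**Significance.** A corrected log2 ratio is called positive/negative when
it exceeds ±threshold with *strict* inequality (±0.29 itself is
non-significant).  The default 0.29 is the 95% envelope of normalized gDNA
ratios (linear 0.82–1.22), read as empirical percentiles rather than
mean ± 1.96·SD.  A read-depth-adaptive mode replaces the constant with the
error-curve bound E(total reads).

## Error models

**Method 1 — gDNA distribution.**  Mean, SD, SEM and the central 95%
percentile interval of normalized gDNA linear ratios, reported on linear
and log2 scales.  Fewer than 20 ratios triggers an instability warning.

**Binomial envelope.**  For X ~ Binomial(N, ½), the bounds are
log2(q/(N−q)) at the exact (1±c)/2 quantiles, truncated to interior counts.
The delta-method limit of the half-width is `z · 2 / (ln2 · √N)`
(z the normal quantile; 0.179 at N = 1,000, 95%), and the exact envelope
converges to it within 2% by N = 10,000.  Real gDNA deviations exceed this
envelope: PCR noise is extra-binomial.

**Method 2 — rectangle.**  E(X) at confidence c is the smallest half-height
such that the rectangle [X, ∞) × [−E, E] contains at least a fraction c of
the (reads, log2 gDNA ratio) points with reads > X — implemented as the
⌈c·n⌉-th order statistic of |log2 ratio|, which is exactly the geometric
adjust-the-lines procedure, deterministic and oracle-testable.  The curve
is swept over X ∈ {500, 1,000, 2,000, 5,000, 10,000, 13,500, 24,300,
50,000} (grid points with <20 supporting measurements are omitted) and
flattened to be non-increasing by raising each bound to the maximum over
higher thresholds — conservative isotonic flattening of sampling-noise
inversions.  Lookup is a step function; read counts at or below the
smallest threshold fall back to the largest bound with a warning.

## Population model of log2AEI distributions

Each regulatory variant v has allele frequency P_v, additive log2 effect
e_v, and LD D′_v to the marker; optional pairwise D′ between variants.
Two-locus haplotype frequencies use the D′-parameterization
(D = D′ · Dmax with the frequency-constrained maximum for the sign of D′),
which guarantees a valid table for any |D′| ≤ 1.  The joint over up to four
variants plus the marker is the maximum-entropy completion of the pairwise
constraints: with only variant–marker tables this is closed-form (variants
conditionally independent given the marker allele); with pairwise
variant–variant tables it is found by iterative proportional fitting to
1e-10 (non-convergence names the infeasible pair).

Diplotypes form by random union of haplotypes (HWE), conditioned on marker
heterozygosity.  Each variant contributes e_v · s_v with phase
s ∈ {+1, −1, 0} (high-expression allele on the M haplotype / on the m
haplotype / homozygous); effects combine **additively on the log2 scale**
(multiplicatively on expression) — the combination rule is declared, not
estimated.  Trans-acting variation scales both alleles equally and cancels
in the ratio; together with unmodeled factors it appears only as the
Gaussian `noise_sd` term.  The predicted distribution is the exact finite
mixture of phase-configuration displacements convolved with that noise.

**Shape classification** of an ordered distribution (≥5 values): `null` if
no value exceeds ±threshold; `uniphasic` if all significant values share a
sign; `biphasic` if the minority sign holds ≥25% of significant values;
`skewed` otherwise.

**Fitting** is a deterministic grid search (the objective is
piecewise-smooth in D′ and the parameter count small; no gradients): for
each candidate (P, e, D′)^k the exact mixture quantiles at Blom plotting
positions (i−0.375)/(n+0.25) are compared to the observed order statistics
by mean squared difference.  Mixture quantiles are inverted on a dense
shared CDF grid (1,024 points, adequate for the 0.1-spaced effect grid).
Near-ties (within 5% relative of the best objective) are broken toward the
smallest total |effect|, then the weakest total linkage — the weakest model
that explains the data, which also makes k=2 fits on single-variant data
collapse to the single-variant solution.  Default k=1 grid: P ∈ 0.1..0.9
(step 0.1), e ∈ −1.5..1.5 (step 0.1), D′ ∈ 0..1 (step 0.125); coarser for
k ≥ 2.  With an error curve and per-observation read depths, the noise sd
is the mean depth-specific bound divided by the curve's normal quantile.

## Synthetic data: what it emulates, and what it does not

Counts: gDNA M-reads ~ Binomial(N, b/(1+b)) with amplification bias b;
cDNA M-reads ~ Binomial(N, b·r/(1+b·r)) with true expression ratio r.
Study-scale generation adds a per-measurement log2-normal bias jitter
(run-to-run PCR variability).  Its default sd (0.1403) is solved so that
the pooled central 95% of null measurements spans ±0.29 under log-uniform
depths over the study's gDNA span (1,079–33,250) — the condition under
which ~5% of null cDNA measurements are called significant at the
envelope, as observed.

The default 70-gene, 52-sample design plants the published composition:
~11% null genes, ~29% weakly regulated (|e| ~ U(0.10, 0.22),
D′ ~ U(0, 0.35)) and ~60% clearly regulated (|e| ~ U(0.3, 0.9),
D′ ~ U(0.25, 1)), single cis variant each, biases U(0.67, 1.5), marker
frequencies spread so heterozygote counts land in the 3–36 range, depths
log-uniform over the observed spans.  The weak/strong boundary ranges were
set analytically from the *realized* (finite-heterozygote, binomial)
probability of crossing the 20%-significant boundary, not tuned on
pipeline outcomes.  Two purpose-built fixtures are constructions rather
than assay emulations and say so in their docstrings: the calibrated gDNA
ratio set (jitter solved so the 95% envelope equals a requested
half-width) and the calibrated error cloud (piecewise-constant
depth-band spreads solved top-band-first so the pooled tail quantiles
equal requested anchors) — they validate the estimators against known
truth.

FASTQ generation plants exact allele counts plus triage classes: a
fraction of reads with random inserts (fail matching), a fraction
truncated before the mSNP, and a full-length fraction (default 85% at
76 bp).  Substitution errors apply across the whole read including the
index.  Not modeled: base-quality profiles, PCR duplicates, indels,
flow-cell artifacts, paired ends.  Passing tests therefore demonstrate
correctness of the computational chain under binomial sampling + log-normal
PCR noise, not robustness to real base-calling error structure.

All randomness flows through numpy's PCG64 (`default_rng`), an
integer-state generator with platform-independent streams; every entry
point accepts a seed and is fully deterministic under it.

## Known limitations and open choices

* One pooled jitter scale for all genes: real per-gene noise is
  heterogeneous, so truly silent genes are rarer in simulation than in the
  assay's report of genes with no significant sample (the simulated
  any-significant gene fraction runs ~2–4 points above the assay's 89%).
* The published overall ±0.29 envelope and the rectangle-method ±0.16 at
  >1,000 reads cannot both arise from one percentile-based noise model
  when nearly all measurements exceed 1,000 reads; the two calibrations
  are therefore kept separate (the ±0.29 reading may reflect
  mean ± 1.96·SD under heavy tails).
* Depth-adaptive fitting uses a single averaged noise sd rather than
  per-order-statistic heteroscedastic noise.
* Identity-threshold matching (0.9) is a stand-in for the original
  external-aligner criteria, which are not recoverable.
* No dominance or epistatic interaction between regulatory variants; >4
  variants are out of scope (enumeration is exact, not approximate).
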