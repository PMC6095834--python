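# Methods

## Screen model

A pooled dropout screen measures, for every hairpin *i* and sample *j*, a
read count *k_ij*. Samples belong to a cell line, a timepoint (T0 after
library selection, T1 after 2–3 weeks of culture) and a replicate. Hairpins
whose knockdown is toxic deplete between T0 and T1; the analysis estimates
that depletion per hairpin, aggregates it per gene, and compares hit
patterns across a genotyped cell-line panel.

### Normalization

Size factors use the median-of-ratios estimator: for each hairpin with
strictly positive counts in every sample, form the ratio of each sample's
count to the hairpin's geometric mean across samples; the sample's size
factor is the median of those ratios. The estimator is invariant to row
order and equivariant to column scaling. Note that scaling one of *m*
columns by λ rescales the geometric-mean reference by λ^(1/m), so all
normalized counts shift by that common factor; ratios of normalized means
(fold changes) are unaffected except through the pseudocount.

### Dispersion

Replicate noise is modelled as negative binomial, Var = μ + αμ². Per
hairpin, α is estimated by method of moments within each timepoint: the
empirical variance of normalized counts minus the shot-noise term
μ·mean(1/s_j), divided by μ², floored at zero and pooled across timepoints
by degrees of freedom. Information is shared across hairpins by a robust
fit (soft-L1 loss, non-negative parameters) of α_fit(μ) = a₀ + a₁/μ; the
working dispersion is max(α_raw, α_fit(μ)), a deliberately conservative
rule that never lets a hairpin borrow a smaller variance than its own data
show. With a single replicate per condition the estimator refuses to run
unless `blind=True` pools all samples (conservative: real T1/T0 signal then
inflates α).

### Depletion test

Counts are summed per timepoint and the test conditions on the grand total
K. Each timepoint's sum is negative binomial with mean q₀·Σs_j and variance
q₀·Σs_j + α·q₀²·Σs_j², where q₀ is the pooled mean of normalized counts.
The two-sided p-value is the conditional probability mass of all splits
(a, K−a) no more likely than the observed one (minimum-likelihood rule).
Enumeration is exact for K ≤ 5000; beyond that the conditional law is
replaced by its moment-matched normal approximation with continuity
correction (the switch point is configurable; the approximation agrees with
enumeration to ~0.3 in log₁₀ p around the switch, far finer than the 0.1
decision threshold it feeds). A grand total of zero returns p = 1.

Fold change is computed on normalized means with a pseudocount c = 0.5
(FC = (mean_T1 + c)/(mean_T0 + c)), used for effect size only, never for
testing. Hairpins with normalized T0 mean below 30 (configurable) are
dropped: a hairpin that never established itself in the pool cannot show
depletion, and its p-value is meaningless.

## Hit calling

Per gene and line, four criteria must all hold:

1. at least one retained hairpin with p < 0.1 **and** FC < 0.3 (the strict
   same-hairpin reading; a gene-level-minimum-p variant is available behind
   `HitCriteria(gene_level_p=True)`),
2. geometric-mean FC of all retained hairpins < 0.8,
3. gene rank ≤ 100 by the second-best-hairpin statistic, and
4. at least two retained hairpins (implied by criterion 3's sentinel).

For criterion 3, retained hairpins are ranked ascending by log₂ FC (ties:
smaller p, then hairpin id — fully deterministic); each gene is scored by
the rank of its second-most-depleted hairpin (genes with fewer than two
hairpins get the sentinel worst score), and genes are ordered by that score
(ties: best hairpin rank, then symbol). Fold change is the ranking score
because it is the only per-hairpin effect statistic the pipeline defines;
the p-value serves as a filter, not a score.

### A known false-positive mode

A single hairpin at FC ≤ 0.33 among four null hairpins already drags the
five-hairpin geometric mean below 0.8, so criterion 2 does not by itself
exclude one-hairpin (off-target-like) genes; only the second-best-rank
criterion does, and it admits genes whose second hairpin drifts modestly
low by chance. On simulations with 2% off-target hairpins this yields a few
such calls per line (raising the per-line false-positive count while recall
stays at 1.0). Because off-target behaviour is a property of the construct,
not the cell line, these calls are genotype-balanced and do not contaminate
the genotype-specificity ranking — which is why the cross-line comparison,
not any single screen, identifies the synthetic-lethal candidates.

## Cohort analysis

The hit matrix is boolean gene × line. Common lethals are genes with hit
fraction ≥ a threshold across all lines, ranked by fraction then mean gene
rank. Genotype specificity of a gene is score = hits_mut/n_mut −
hits_wt/n_wt ∈ [−1, 1], ranked descending with the per-gene two-sided
Fisher exact p as tiebreak; the ranked list subsumes any particular cutoff
for "preferentially mutant". Fisher tests use the minimum-likelihood
two-sided rule (every table with the same margins no more probable than the
observed one), delegated to scipy and cross-checked in the test suite
against exhaustive hypergeometric enumeration.

Drug sensitivity: replicate signals are averaged per dose, relative growth
is the treated mean over the untreated mean, and a line is sensitive iff
relative growth < 0.5 (strict) at the 250 nM reference dose. Sample size
for a two-group comparison uses the normal-approximation closed form
n = ⌈2(z₁₋α/₂ + z_power)²·(CV/Δ)²⌉ with SD expressed as a coefficient of
variation of the control mean and the effect as a relative reduction — the
closed form consistent with the four standard inputs (α = 0.05, power 0.8,
Δ = 0.5, CV = 0.25 → n = 4).

## qPCR quantification

ΔΔCt assumes amplification efficiency exactly 2.0 (configurable); replicate
Cts are averaged on the cycle scale; relative expression is
2^−(ΔCt_treated − ΔCt_control) with ΔCt = Ct_target − Ct_reference.
ChIP percent-of-input adjusts the input Ct for the input dilution
(Ct_input − log₂(1/fraction)) and returns 100·2^(Ct_input_adj − Ct_IP). The
default input fraction is 1% and must be supplied for real experiments.

## TSS metaprofiles

BED and bedGraph are treated as 0-based half-open throughout. The TSS is
the interval start on '+' and end − 1 on '−'. Windows are
[tss − flank, tss + flank) with flank 3 kb and 50 bp bins (120 bins) by
default; each bin holds the mean per-base value (not the sum), which makes
profiles comparable across window counts; minus-strand rows are reversed so
downstream is always rightward. Mirror symmetry is exact around the
half-open centre: mirroring regions' strands together with the track
(interval [s, e) → [2·tss − e, 2·tss − s)) leaves the profile unchanged.
The profile is the per-bin mean across regions with standard error
sd/√n (0 when n = 1). Positions off the covered intervals, off the
chromosome start, or on chromosomes absent from the track read as zero
(absent chromosomes are tallied in a warning count). No cross-track
normalization is applied; comparability of, say, treated vs control tracks
is the caller's responsibility.

## Synthetic screens

The generator emulates the study design directly: 535 genes × 5 hairpins,
a 14-line panel (5 wildtype / 9 mutant), triplicate T0/T1 samples and
1000× coverage by default. Choices:

- **Baseline skew.** Hairpin baseline abundances are log-normal with sd 0.5
  in log₁₀ — TRC-style libraries are strongly uneven, which makes
  normalization and the abundance floor do real work.
- **Counting model.** Sequencing depth per sample is coverage × n_hairpins
  reads allocated multinomially over hairpins, which couples hairpins the
  way a sequencer does; replicate overdispersion enters as gamma noise on
  the expected proportions (the gamma-Poisson construction of the negative
  binomial), with dispersion 0.05 by default — a typical magnitude for
  biological replicates of count assays.
- **Effects.** Planted lethal genes carry per-hairpin true fold changes,
  drawn uniform on [0.1, 0.3] by default (strong, clearly sub-threshold
  depletion; no effect-size distribution is published for true lethals, so
  this is a generator choice). Common lethals act in every line; genotype
  lethals only in mutant lines. 2% of hairpins in neutral genes receive an
  off-target fold change uniform on [0.2, 0.8], applied in every line —
  single rogue constructs that exercise the second-best-rank safeguard.

What the generator does **not** model: infection/selection dynamics and
multiplicity of infection, read-level errors (counts are generated
directly), PCR jackpotting, hairpin-efficacy variation within lethal genes,
and any correlation structure between cell lines beyond genotype. Passing
recovery tests therefore shows the statistics behave correctly under the
assumed count model, not that real screens meet those assumptions.

## Problem sizes and numerical choices

The test suite and acceptance script run the full 14-line, 2675-hairpin
cohort once (about half a minute), ten single-line null screens of the same
library size, and property checks (exact-test enumeration vs oracle up to
K = 200, Fisher enumeration up to table totals of 40, ranking brute force
up to 50 hairpins). Dispersion fits fall back to a constant when fewer than
two hairpins have positive means. Ties in the exact tests are resolved with
a 1 + 10⁻⁷ relative slack on the observed probability, the convention that
makes "no more probable than observed" robust to floating-point noise.

## Limitations

- The depletion test is the classic conditional NB exact test; it predates
  shrinkage-based GLM approaches and is conservative at small counts
  (p-values are discrete and ≥ the uniform on null data).
- The unadjusted p < 0.1 gate mirrors the screening convention; a
  Benjamini–Hochberg column can be added downstream but is deliberately not
  used for hit gating.
- Barcode counting is exact-prefix matching (default 21 nt) with an
  ambiguity discard rule; no mismatch tolerance or quality trimming.
- The specificity ranking orders genes; where to cut the list for
  follow-up is a judgement the package does not make.
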