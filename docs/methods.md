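# Methods

## Estimators

All window statistics are ratios of sums over sites ("count-ratio" or
"ratio of averages" estimators), never means of per-site ratios.  For a
window W and population p with per-site ALT counts c₁ and genotyped
haplotype counts n:

- π(W, p) = Σ_{s∈W} c₀c₁ / Σ_{s∈W} n(n−1)/2, over sites with n ≥ 2;
- D_XY(W, A, B) = Σ (c₀ᴬc₁ᴮ + c₁ᴬc₀ᴮ) / Σ nᴬnᴮ, over sites with at least
  one genotyped haplotype on each side;
- Hudson's F_ST(W, A, B) = Σ num / Σ den with the sample-size-corrected
  site numerator num = (p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1) and
  denominator den = p₁q₂ + p₂q₁, over sites with n ≥ 2 on both sides.
  An uncorrected plug-in form is available via `fst_corrected=False`.
  Negative window values are retained (no clamping at 0) so that the
  downstream z-standardization is unbiased.

These choices make the estimators invariant to adding fully-missing
genotypes and unbiased under per-genotype missingness: a thinly genotyped
site contributes proportionally fewer comparisons.  Invariant sites enter
the π and D_XY denominators; without them the statistics would not be on
a per-bp scale.  A window's statistic is undefined (NaN), never zero,
when its denominator is empty; undefined windows are excluded from
standardization and never classified.

Tajima's D uses the fixed-n formula with the classical constants
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂): per window and population, sites with
any missing genotype in that population are excluded (complete-case) and
n stays at the full haplotype count.  A per-site-n variant is out of
scope.  D is undefined when S = 0.

Identity used by the F_ST test oracle: the corrected numerator equals
d_xy − (h_A + h_B)/2 with h the unbiased within-population pairwise
difference proportion, which lets exhaustive pair enumeration reproduce
the estimator exactly.

## Filters

Mirroring VCFtools semantics on the study's joint VCF: genotypes need
quality ≥ 20 and depth in [15, 50] (inclusive bounds), failing genotypes
become missing; sites are dropped when more than 10% of genotypes are
missing (inclusive at exactly 10%) or when the record carries more than
two alleles.  The missingness denominator is all samples in the VCF
(ingroup + outgroup), switchable to ingroup-only — the original analysis
filtered one joint VCF and does not state which was used.  Filtering is
idempotent.

## Windows

Non-overlapping tiles of `window_bp` (default 10,000 bp) over each
manifest region, falling back to a chromosome-level tiling (flagged) for
sites outside every region.  Window w covers 1-based positions
[(w−1)·L+1, w·L]; trailing windows may be short.  The catalog enumerates
every tile of every region, so siteless windows appear with a site count
of zero.  The original description says "sliding window" without a step,
so non-overlapping tiles — the default of the windowed-statistics tool
it cites — are used; the window length is a parameter.

## Scenario classification

Per pairwise comparison, window F_ST, D_XY and the two populations'
averaged π are z-standardized against the comparison-wide mean and a
population (divide-by-N) standard deviation (the sample/population choice
is not stated anywhere; ddof is a parameter).  Rules are evaluated in
fixed precedence (gene flow, allopatric, recurrent, balancing; first
match wins), which resolves the genuine overlap between the allopatric
and recurrent rules.  The "< k SD" clauses are read against the band
boundaries drawn in the study's scatter figure — upper boundary +3 SD,
lower boundary −1 SD — so "< 3 SD" means z < +3 and "< 1 SD" means
z < −1; an all-above-mean reading is available via `semantics="upper"`.
F_ST outlier windows use strict z > 3 and are mapped to genic regions by
interval overlap.

## dN/dS

The 4-fold-degeneracy approximation is taken literally: codon positions
1–2 are always non-synonymous sites, position 3 always synonymous, no
genetic-code lookup — this knowingly misclassifies some codons and is the
approximation the scan is defined by.  Leading bases before the frame
offset and trailing partial codons are excluded.  A site is covered for a
gene × population when ≤ 50% (inclusive) of the population's genotypes
are missing and ≥ 1 outgroup allele is observed; a fixed difference is a
covered site whose observed population and outgroup allele sets are
disjoint (on biallelic data this coincides with "both monomorphic for
different alleles"; a strict-monomorphism rule is available and tested to
agree).  dN = fixed-nonsyn / covered-nonsyn sites, dS analogously; genes
need ≥ 1 fixed site of each class for a ratio.  Outliers are strictly
above mean + 3·SD of each population's ratios; the divergent-selection
set is the intersection of the union of F_ST-outlier genes over pairs
with the union of dN/dS-outlier genes over populations.

## Synthetic-data generator

The generator is the package's testbed: it emulates the study design
(five unequal diploid populations plus a two-individual outgroup,
~4,200 regions of which 133 are non-genic, 10 kb windows, per-genotype
depth/quality and missingness) with a model simple enough to verify in
closed form.

Per site, independent layers:

1. **Shared ancestral polymorphism.** A site is ancestrally variable
   with probability s, frequency drawn from the neutral spectrum
   f(x) ∝ 1/x truncated below at 10⁻³ (the role of 1/2N for N = 500);
   s is calibrated so that s·E[2p(1−p)] = θ_anc (default 0.003, matching
   the study's observed π ≈ 0.003).
2. **Drift.** Population i's frequency is a Balding–Nichols perturbation
   with F_i = 1 − exp(−b_i/θ_anc), the coalescent identity T/2N = b/θ
   applied to its branch length; drift leaves E[D_XY] unchanged and
   shrinks E[π] by (1−F).  A `drift_scale` multiplier is exposed.
3. **New fixed differences.** On a star tree, population i privately
   fixes derived alleles at rate b_i per site, so a pair's added expected
   divergence is b_i + b_j = 2μT and E[D_XY] = θ_anc + 2μT exactly (up to
   a −2b_ib_j collision term ≲ 10⁻⁶).  Per-pair divergence input is
   fitted to star branch lengths by least squares; a star tree cannot
   represent an arbitrary hierarchical matrix exactly, which is accepted
   as a simulator limitation.  Migration between a flagged pair copies a
   fraction (default 0.5) of private mutations to the partner, shrinking
   that pair's realized divergence.
4. **Expansion mode** (default on, as all five study populations show
   negative Tajima's D): private low-frequency variants at 0.6·s per
   site with frequencies from 1/x on (10⁻³, 0.1), producing the excess of
   rare alleles characteristic of growth after a bottleneck.
5. **Outgroup divergence** at 0.02 per site (congeneric outgroup),
   uniformly over positions, giving a neutral dN/dS background near 1.

Depth is negative-binomial (mean 30, variance 90, so ~5% of genotypes
fall below DP 15 and ~2% above DP 50, giving the filters real work);
genotype quality is 99 with a 2% chance of 10; genotypes go missing
outright at `missing_rate` (default 5%).  All randomness flows from one
integer seed; identical config + seed gives byte-identical output files.

**Scenario injections** rescale a window's generative rates so its
expected statistics land inside the target rule region of z-space.  The
default effects were derived from the closed-form expectations above
(E[π] = s'·h·(1−F), E[D_XY] = s'·h + b'ᵢ + b'ⱼ, F_ST ≈ 1 − H_w/H_b) and
then verified by simulation:

| scenario   | shared × | divergence × | extra balanced sites |
|------------|----------|--------------|----------------------|
| gene flow  | 0.4      | 8            | —                    |
| allopatric | 0.25     | 3            | —                    |
| recurrent  | 0.5      | 1.2          | —                    |
| balancing  | 1.0      | 0.5          | 0.7·s at U(0.3, 0.7), drift ×0.3 |

Recurrent selection is intrinsically marginal by construction — the rule
demands z_fst ∈ (1, 2] (above it the higher-precedence allopatric rule
absorbs the window) while per-window Monte-Carlo noise on F_ST is about
one z-unit — so its recall is modest (~0.2–0.3) but still far above the
neutral false-labeling rate, which is the property that matters.

**Coding injections** place the requested number of extra
population-derived fixed differences at non-synonymous/synonymous
positions on top of the background outgroup divergence.  The
strong-signal outlier demonstration uses background divergence 0.04
(≈ 20 synonymous events per 500-codon gene, which keeps the neutral
ratio's 1/dS noise in check) and +200 non-synonymous fixations,
putting injected genes at ≈ 5.5–6× the neutral mean ratio.

### What the generator does not emulate

No recombination maps, no linkage (sites are independent), no
sequencing-error model, no read-level simulation, no fitted
isolation-with-migration demography, and a star topology rather than the
study's hierarchical population tree.  Passing tests therefore show that
the estimators, rules and gates are implemented correctly and behave as
theory predicts under a clean neutral/selection model — not that the
pipeline's biological conclusions transfer to any particular real
dataset.

## Numerical choices and degenerate inputs

Statistics with empty denominators are NaN and propagate as "undefined",
never zero.  Standardization with < 2 defined windows or zero SD flags
the comparison and classifies nothing.  dN/dS with < 2 defined ratios or
zero SD yields no outliers, flagged.  Half-called genotypes are collapsed
to missing at read time.  Region lookup assumes non-overlapping regions
per chromosome (last-start-before-position).  Outlier thresholds are
strict inequalities (z > 3, ratio > mean + 3·SD).  Ties in rule
evaluation cannot occur (first match wins).

## Problem sizes

The validation suite uses: 2,000 windows × 1 kb for the
E[D_XY] = θ + 2μT calibration (Monte-Carlo relative error ≈ 1% against
the 5% band) — run with expansion and missingness off, since the closed
form is the neutral-baseline expectation and expansion adds private
variation that intentionally shifts D_XY; 600 windows for the
undiverged-pair F_ST null and the neutral-equilibrium Tajima's D mean;
500 windows × 8 diploids for the split-population D_XY ≡ π identity;
700 windows × 5 kb with 7 injections per scenario for classifier
recovery; 500 genes × 250 codons for the neutral dN/dS calibration; and
300 genes × 500 codons for outlier-recall.  Oracle-equivalence fixtures
stay at ≤ 5 diploids × ≤ 30 sites where exhaustive enumeration is exact.

## Known limitations

The star-tree divergence model and independent-site assumption understate
the variance of window statistics relative to linked real data; the
z-thresholds are therefore easier to calibrate here than in practice.
The simulator's F_ST level is an emergent consequence of θ, b and F
rather than an input.  The band semantics for "< k SD" is an
interpretation of an ambiguous rule statement (the alternative is one
flag away).  dN/dS ignores within-population polymorphism beyond the
fixity test and uses no codon model.
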