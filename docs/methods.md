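# Methods

This note documents the models implemented in `beanqtl`, the defaults and
why they were chosen, what the synthetic populations do and do not emulate,
and the numerical conventions that matter for reproducing the outputs.

## Population simulator

**Model.** Two fully inbred founders are crossed; the F1 is advanced by
single-seed descent for `selfing_generations` rounds (default 6, i.e. F7).
Each meiosis draws a Poisson number of crossovers per chromosome with mean
`crossover_rate` (Morgans; default 1.3, giving ~130 cM chromosomes as in a
legume-sized genome) and places them uniformly — a Haldane (no-interference)
process, chosen deliberately so that the Haldane map function downstream is
exactly consistent with the generative model. Lines are stored as founder
mosaics (breakpoints + founder labels per haplotype), which tile each
chromosome without gaps or overlaps by construction.

**Observation layer.** SNP sites are placed uniformly at `snp_density` per
Mb; each homozygous call flips to the opposite homozygote with probability
`genotyping_error_rate` (default 1%) and any call drops to missing with
probability `missing_rate` (default 10%) — scales typical of ~6x skim
resequencing. Heterozygous observed calls arise only from true residual
heterozygosity; parents are modelled error-free (they are sequenced ~35x in
the study design this emulates). The generic desk-scale default of 50
SNPs/Mb is kept on `SimConfig`, but the pipeline driver and analysis scripts
simulate at 300 SNPs/Mb (~30 per 100 Kb window) so that the "< 20 SNPs ⇒
missing window" rule operates rather than blanking the grid.

**Segregation distortion.** A `DistortionLocus(chrom, pos, paternal_prob)`
biases each meiosis: the transmitted allele at the locus is resampled (by
rejection over whole-chromosome gametes, preserving linkage) to match a
Bernoulli(`paternal_prob`) draw. Over six selfings a per-meiosis bias of
0.85 drives ~97% of lines to paternal fixation at the locus, with the skew
decaying along the chromosome.

**Phenotypes.** For each trait, value = baseline + Σ_j a_j·x_j + env shift +
residual, with x ∈ {+1, 0, −1} for maternal/het/paternal at each planted
QTL. The residual variance is solved from the planted `target_pve` values
using Var(x) = 1 − (1/2)^g, so the QTLs jointly realise their target
variance fractions within an environment; environment shifts are shared
N(0, `env_effect_sd`²) offsets. Setting `residual_sd` explicitly overrides
the solver.

**What the simulator does not emulate.** Read-level sequencing (depth,
allele-balance errors), crossover interference, selection during line
development, non-additive (dominance/epistatic) trait architecture, and
genotype-by-environment interaction beyond additive environment shifts.
Passing tests therefore demonstrate correctness of the pipeline's
algorithms under a clean additive Haldane world, not robustness to every
artefact of real resequencing data.

## SNP filtering

Sites are kept when both parents are homozygous for different alleles
(everything else is uninformative for a biparental map) and when a
two-sided exact binomial test of the population's A:B counts against 1:1
gives p > 0.05. The source protocol states only "P > 0.05" without naming
the test; the binomial segregation test is the only population-level
quantity available before a map exists, and it is isolated in
`filtering.consistency_pvalues` so it can be swapped. A consequence worth
knowing: this filter *removes* genuinely distorted markers, so extreme
distortion reaches the bin map only where linkage to the distortion locus
has decayed — at desk scale the distorted chromosome collapses to a few
bins, which is also the qualitative signature of the shortest,
distortion-rich chromosome in the original map. Sites with no A/B calls at
all carry no evidence either way and are retained, so `p_min = 0` reduces
exactly to the parent-homozygosity rule.

## Bin map construction

Windows are fixed, non-overlapping 100 Kb tiles (a "sliding" window with
step = width; the step is configurable). A unit-step sliding window would
produce window-fraction-sized bins, contradicting the reported bin
granularity. Per line and window the call is the majority vote of
non-missing SNP codes; ties and windows with fewer than `min_snps` (20)
SNPs are missing, terminal stubs shorter than the window width are missing,
and windows whose het votes strictly exceed the homozygous votes are
pre-labelled H.

Smoothing is a two-state {A, B} Viterbi HMM per line and chromosome:
emission error ε (default 0.05) is the probability a window's majority vote
contradicts the underlying state; the per-window transition probability
defaults to `window_bp × 2 / chrom_length_bp` (two crossovers per
chromosome, genome-scaled). H and missing windows emit uninformatively; H
windows are re-inserted in the smoothed path afterwards. Ties in the
Viterbi recursion prefer staying in the current state, making paths
deterministic. Lines with no informative window on a chromosome stay
missing there.

Breakpoints are transitions between consecutive non-missing path entries,
with the junction coordinate at the right window's start. Bins are the
union partition of all lines' breakpoints; all-missing intervals are
dropped and adjacent bins with identical population vectors merged.

**Resolution limit.** With 100 Kb windows, a founder segment shorter than
about two windows is invisible in principle: the Viterbi penalty for a
two-window excursion exceeds its emission support at the default ε and
transition scale. In an F7 population, where 12 meioses have accumulated,
roughly 15% of true genotype transitions bound such sub-resolution
segments. Recovery statistics are therefore quoted over window-resolvable
crossovers (both flanking segments ≥ 2 windows), where the pipeline
recovers ≥ 95% to within 1.5 windows with < 0.2 spurious breakpoints per
line at 1% genotyping error.

## Genetic map

Bins keep their physical order (they are anchored to reference
chromosomes; no de novo linkage grouping). Between adjacent bins, R_obs is
the fraction of pairwise-informative lines (non-H, non-missing at both)
whose genotypes differ; pairs with fewer than 10 informative lines are
flagged low-confidence. The meiotic fraction is r = R/(2(1−R)) capped below
0.5 — the selfed-RIL (Haldane–Waddington) limit — and distances default to
Haldane (the default of the standard R mapping package), with Kosambi
selectable. Because the correction assumes full inbreeding, map recovery is
validated on effectively fixed lines (12 selfings), where a simulated
100 cM chromosome is recovered unbiased (±3 cM SD at 400 lines, 100
markers); at F7 the same estimator reads ~5% short — a documented bias, not
corrected, since the study population is treated as fully inbred by the
standard transform too. Collinearity between physical midpoints and cM
positions (Spearman) is reported per chromosome as a pipeline self-check;
it equals 1 by construction when the order is physical.

## Phenotype statistics

Combined-environment values are per-line arithmetic means over the
environments with data; report tables round half-up to 2 decimals (the
convention that reproduces the published combined means). Variance
components come from a two-way line × environment decomposition of line
means: with one value per line and environment, G×E and residual are
confounded and enter together as MS_GE, so h² = σ²_G/(σ²_G + MS_GE/e) with
σ²_G = (MS_G − MS_GE)/e truncated at zero (entry-mean basis; the source
does not state its formula, and this is the standard choice for line-means
data). Balanced data uses the exact closed-form ANOVA; unbalanced data is
restricted to lines observed in every environment (with a warning) and fit
by OLS. GCV = 100·σ_G/mean; a single-environment slice falls back to the
phenotypic CV. The anthocyanin conversion A530 − 0.25·A657 is floored at
zero with a warning.

## Composite interval mapping

The scan is Haley–Knott-style regression on a 1 cM grid (plus all marker
positions). The expected genotype at a test position conditions on the
nearest flanking bins through the two-state RIL chain with transition
probabilities R = 2r/(1+2r), r from the inverse map function; H or missing
flanks are uninformative, and a line unknown on both sides contributes its
prior expectation 0. Cofactors are chosen by forward stepwise regression
(entry p < 0.01, default cap 5, exact-duplicate bins deduplicated) and
dropped within 10 cM of the test position. LOD =
(n/2)·log10(RSS_reduced/RSS_full), computed by residualising the test
genotype and the trait against the active cofactor set (QR projection), so
a scan over thousands of permutations vectorises. With zero cofactors the
scan is exactly simple interval mapping.

Permutation thresholds shuffle phenotype values across lines (genotype
structure intact), record the genome-wide maximum LOD per permutation, and
take the empirical (1−α) quantile (upper order statistic); cofactors are
held fixed across permutations. Calibration at desk scale (two 60 cM
chromosomes, 120 lines, 1000 permutations, 400 independent null traits)
puts the genome-wide type-I error at 3.5–5.5% across seeds.

QTLs are local maxima above the threshold, merged within 10 cM. The LOD−1
support region is found on the scan grid and then the two crossings of
(peak − 1) are interpolated on the piecewise-linear LOD curve before
mapping to bin bounds — without the interpolation the discrete grid
truncates the support by up to one step per side, which in coverage
simulations cost ~20% coverage for a strong QTL. PVE uses the LOD identity
100(1 − 10^(−2·LOD/n)) (exactly the regression R² for a single-marker
model); the additive effect is half the difference between the A and B
class means at the leading bin, so a positive sign means the maternal
allele increases the trait. Naming is `qTRAIT` + chromosome, with `-1, -2`
suffixes in positional order when a chromosome carries several QTLs for a
trait. Across environments, records merge when their intervals overlap and
their peaks lie within 5 cM; the merged record keeps the strongest call and
lists all detecting environments with "combined" last.

At the study's population size (n = 211) a planted QTL at 56% PVE on a
0.7 cM-spaced map is detected in 100% of replicates with its true position
inside the LOD−1 interval in ≥ 95% (100 replicates, 1000-permutation
thresholds).

## Map summary conventions

The per-chromosome report counts gaps as bins − 1 per chromosome. The
derived percentages reproduce the published arithmetic only under mixed
denominators, which are fixed here exactly as the printed values imply:
bin-length and adjacent-distance classes divide by the total bin count;
gap-length classes divide by bins − chromosomes; the *average* gap length
divides by total bins − 1 (the printed average's divisor), with the
bins − chromosomes alternative also computed (`gap_avg_kb_alt`) so neither
convention is hidden. Published per-chromosome Mb/cM rows are half-up
rounded and sum 0.01 short of the printed totals, so recomputed averages
take the printed totals row while the integer bin count is summed from the
rows. Report values round half-up at 2 decimals.

## Problem sizes used in verification

Chosen once as the smallest scales at which Monte-Carlo error is well
inside each tolerance: heterozygosity law 4000 lines × 200 loci (3 SE
band); recombinant-fraction law 10 000 lines at r = 0.1, 14 selfings
(3 MC-SD band); map recovery 400 lines × 100 markers on one 100 cM
chromosome; CIM calibration 400 null trials × 1000 permutations on a
reduced two-chromosome genome; power/coverage 100 replicates at n = 211 on
a three-chromosome genome with 0.7 cM marker spacing (the study map's
density); HMM oracle 60 random chains of ≤ 12 windows against exhaustive
enumeration.

## Known limitations

* The RIL correction and CIM genotype expectations treat lines as fully
  inbred; at F7 maps read a few percent short and ~1.5% of calls are H.
* The two-state HMM cannot represent heterozygous tracts; H windows are
  carried through unsmoothed, which is adequate at ≤ 2% heterozygosity but
  not for earlier generations.
* Window-scale binning cannot recover founder segments shorter than ~2
  windows; sub-window double crossovers are silently absorbed.
* The segregation-consistency filter and segregation-distortion reporting
  are in tension by design (see SNP filtering above).
* Permutation thresholds hold cofactors fixed; under strong polygenic
  backgrounds a full re-selection per permutation would be slightly more
  conservative.
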