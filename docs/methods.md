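# Methods

`ecoparallel` tests whether replicated montane/alpine ecotype pairs of a
plant species diverged through shared or non-shared molecular routes. The
package implements five linked analyses — demographic model selection,
per-pair differential expression, gene-reuse repeatability statistics,
conditioned redundancy analysis, and an FST-outlier scan — together with
synthetic-data generators that reproduce the study design so every stage is
testable without sequencing data. This note records the models, the
defaults and why they were chosen, and the places where the design was
genuinely open.

## Demographic models and inference

Four demes are modelled: an alpine (A) and a montane (M) population at each
of two localities. Two rooted histories are contrasted. Under
`two_origins`, the ecotypes arose independently at each locality: backward
in time, A and M of locality one merge at T2, those of locality two at T3,
and the two locality ancestors merge at T1. Under `one_origin` each ecotype
arose once: the alpine demes merge at T2, the montane demes at T3, and the
ecotype ancestors at T1. T1 always pre-dates T2 and T3; both orders of
T2/T3 are representable. Each topology is evaluated under strict isolation
(SI) and isolation-with-migration (IM, continuous backward migration).
Times are in generations; a generation-time scalar (default 1 year, option
3) is applied only when reporting times in years, never during inference.

**Simulator.** The structured coalescent is simulated directly (Gillespie
event loop, numba-compiled): within-deme coalescence at rate k(k−1)/(4Ne)
with Ne in diploids, per-lineage backward migration m[d,j], and instantaneous
deme mergers. Each lineage is tracked only through its descendant
configuration (how many sampled haploids of each deme it subtends), and
branch lengths are accumulated per configuration; under infinite sites the
expected count of segregating sites with a given joint frequency is
proportional to these lengths. The simulator was validated against msprime
on matched models (total variation distance of normalized joint spectra at
Monte-Carlo precision) and against closed-form expectations (mean TMRCA =
2Ne for n = 2; unfolded SFS ∝ 1/i; pairwise diversity 4Neμ).

A per-genealogy event budget (default 10^6 events; 4,000 during fitting)
guards against runaway regimes: migration rates approaching the upper prior
bound of 2 per lineage per generation imply millions of migration events
per genealogy. During optimization such parameter regions are reported as
infeasible and receive a penalized objective; this effectively restricts
the *searchable* migration range to roughly m ≤ 10⁻³ at desk-scale effort,
far above the rates the fitted models actually support.

**Likelihood.** The data are folded joint SFS for all six deme pairs.
Folding keeps cell (i, j) when i + j < (n1 + n2)/2; on the anti-diagonal
tie the cell with the smaller first-population count is kept, and only the
self-image double tie splits half-and-half. Monomorphic-in-pair mass (cell
(0,0) after folding) is excluded throughout, which makes the normalized
expected spectrum — and hence the composite likelihood — invariant to the
mutation rate. The objective is the multinomial composite log-likelihood
summed over pairs, with expected cell probabilities floored at 1/(10·n_sims)
so unvisited Monte-Carlo cells do not contribute −∞. The saturated bound
`max_obs_lhood` (observed proportions plugged in) gives the fit gap
ΔL = lnCL_obs − lnCL_est; AIC = 2k − 2·lnCL_est in natural-log units, with
log10 values also reported.

**Optimizer.** Multi-start Nelder–Mead on transformed parameters: log10 Ne
per deme, log10 T1, and fractions u2, u3 ∈ (0.02, 0.98) with T2 = u2·T1,
T3 = u3·T1 — the ordering constraint holds by construction (and T2/T3 may
drop below the 1,000-generation prior floor; the search over ratios is
better behaved than a constrained box). IM adds log10 within-locality and
between-locality migration rates (two parameters rather than a free 4×4
matrix: with six spectra from 24 haploids the full matrix is far past
identifiability at this scale). Because the likelihood ignores the mutation
rate, μ is held at the geometric midpoint of its prior and not counted in k
(SI: k = 7, IM: k = 9). Common random numbers (one simulation seed per fit)
make the Monte-Carlo objective deterministic for the optimizer; every
restart is logged. IM fits are warm-started: each restart first optimizes
the no-migration subspace (migration pinned at its lower bound) and then
frees the two migration rates from a low initial value. This matters in
practice — with cold 9-parameter starts the optimizer frequently fails to
reach the basin where the topologies separate, and one-origin-plus-
migration histories with recent splits pushed toward the root can then
spuriously outscore the generating two-origins model; warm-started fits
recover decisive (thousands of log-units) likelihood gaps in favor of the
generating topology. An optional `max_split_fraction` bound further
restricts the search to clearly-separated-split histories, applied
symmetrically to all compared models. Search bounds default to the study
priors: Ne 50–50,000
(alpine) and 50–5,000 (montane) diploids, T 1,000–100,000 generations,
μ 10⁻¹⁰–10⁻⁸, m 10⁻⁹–2 (the printed lower bound "10e-10" is read literally
as 1e-9; both readings are configurable).

Ancestral deme sizes are tied to the sum of the merging demes' sizes by
default (an `ancestral_Ne` option frees them); whether the original
analysis tied or freed them is not documented, and tying keeps k small at
desk scale.

## Popgen summaries

π per site uses the unbiased per-site estimator 2p(1−p)·n/(n−1); θ_W is
S/(a_n · covered sites); Tajima's D uses the 1989 constants and is reported
as undefined (NaN) for S = 0 or n = 2 (zero variance). Windows are 50 kb
with 10 kb steps, half-open, with per-window estimates divided by the
covered-site count.

Differentiation uses the Hudson-class estimator of Bhatia et al. (2013):
per-site α = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) over
p1(1−p2) + p2(1−p1), combined as a ratio of sums (never a mean of
per-site ratios) per gene or over all jSFS cells for genome-wide values.
The same estimator is used for per-gene scans and global summaries.
Outliers are the top ⌈α·G⌉ genes by FST among the G genes with defined
values (α = 0.05 default) — the unique convention consistent with flagging
165 of 3,300 and 141 of 2,811 — with boundary ties broken by gene id for
determinism. The DEG-vs-random FST comparison is a two-sided permutation
test on the difference of means with the add-one (never report p = 0)
correction.

## Differential expression

Genes with mean counts-per-million ≤ 1 (cpm on raw library sizes) are
removed. Normalization is weighted trimmed-mean-of-M-values: reference =
sample whose upper-quartile cpm is closest to the mean upper-quartile;
two-sided trims of 30% on M and 5% on A; inverse-asymptotic-variance
weights; factors rescaled to geometric mean 1. At realistic gene counts the
factors agree with edgeR's `calcNormFactors` to a fraction of a percent
(cross-checked in the test suite); exact numerical equivalence with any
published fitter is explicitly not a goal — the contract is calibration
(type-I error and FDR control) and power on negative-binomial data, because
the downstream claims rest on DEG-set overlaps, not on a particular fitter.

The per-gene model is negative binomial with a log link and one mean per
pair × ecotype cell (8 cells), with effective library sizes as offsets.
Cell means are independent one-parameter Newton fits, so the reduced model
for pair p (that pair's two cells merged) only refits the merged cell.
Dispersion is estimated per gene by Cox–Reid adjusted profile likelihood on
a 24-point grid over 10⁻⁴–10, moderated toward the all-gene average APL
curve with prior weight prior_df/residual_df. The default prior_df = 40 is
deliberately strong: with the true dispersion supplied the LRT is exactly
χ²(1)-calibrated even at 3 replicates, but plug-in dispersion noise at
weaker moderation inflates the deep tail where BH rejections live (measured
~2.5× at p < 10⁻³ with prior_df = 10 on null data). Strong shrinkage
restores tail calibration at the cost of some robustness to genuine
per-gene dispersion heterogeneity; `prior_df` is exposed for data where
that trade-off should go the other way. Each pair's ecotype contrast is a likelihood
ratio test against χ²(1); BH adjustment is applied across genes within each
pair (per-pair DEG lists are the reported unit). logFC is log2 of fitted
cell means with an offset of half a count per mean library, avoiding
infinite fold changes at zero counts.

## Repeatability statistics

Gene sets live over an explicit background: for DEG statistics the
cpm-filtered gene universe, for FST-outlier statistics the genes with
defined FST in both pairs. Implemented measures: Jaccard index; exact
hypergeometric upper-tail overlap p; the k-way generalization (exact
distribution of the intersection of independent uniform fixed-size subsets
via inclusion–exclusion, computed in exact integer arithmetic because the
alternating sum is catastrophically cancellation-prone in floating point);
the analytic C-score (x − E)/σ under the hypergeometric null; a
permutation-standardized global score (observed count of genes used by ≥ 2
replicates vs. same-size random sets); and sharing partitions (genes in
exactly/at least k sets). Category enrichment is a flat one-sided Fisher
test with BH correction — DAG-aware conditioning of ontology terms is out
of scope — plus a direction z-score (n_up − n_down)/√(n_up + n_down) from
the logFC signs of set members, the natural reading of a fold-change-based
term score.

## Conditioned RDA

The expression matrix (cpm after the DE filter, raw scale by default with a
log2(cpm+1) option) is centered per gene; the response and the ecotype
indicator are residualized on the pair indicators (the Condition step);
the residualized response is regressed on the residualized ecotype, and the
SVD of the rank-1 fitted matrix gives the single constrained axis. Total
inertia decomposes exactly (machine precision) into conditioned +
constrained + unconstrained. Gene scores are loadings scaled by the
singular value (scaling-2 convention); only their z-transform matters for
outlier calling at |z| > 2 and |z| > 2.6, which is scaling-invariant.
Because the reported constrained percentage could be taken against total or
conditioning-removed inertia, both are emitted; constrained/total is
primary. Significance is a permutation ANOVA of the pseudo-F
(SS_constrained/1)/(SS_residual/df) with ecotype labels permuted within
pair blocks — the design is balanced and pairs are the nuisance, so
within-block label permutation is the exchangeable scheme here (residual
permutation is the common alternative; a flag switches). Fewer than n_perm
distinct arrangements triggers exact enumeration with a warning.

## Synthetic data

`gen_expression` emulates the common-garden design: 4 ecotype pairs × 2
ecotypes × 3 replicates. Gene baselines are log-normal (σ = 1.5 on the log
scale, a typical RNA-seq abundance spread), libraries log-normal around 2
million reads (desk scale), counts negative binomial with dispersion 0.1
(typical outbred-plant value). A fraction frac_de of genes is DE per pair
(default 5%), of which frac_shared (default 2%) are shared across all four
pairs with consistent direction — the genetic-redundancy dial; remaining
DE genes are strictly pair-private. Signed log2 fold changes are drawn with
magnitude ~N(2, 0.5), split symmetrically between ecotypes. A truth table
records every gene × pair assignment. What this generator does *not*
emulate: gene–gene correlation, length/GC biases, mapping artefacts and
outlier samples — so passing tests demonstrate calibration and recovery
under the assumed NB model, not robustness to real-data artefacts.

`gen_genetic` draws per-site allele counts for the four demes from a
demographic model (counts oriented to the globally minor allele), with
optional depth-based binomial read resampling (Poisson reads per
population at `mean_depth` per haploid, error-rate allele flips) to emulate
noisy low-coverage genotyping, and writes folded jSFS files for all six
pairs. The default `study_model` places parameters mid-prior: alpine
Ne 20,000, montane Ne 3,000, splits at 50,000/15,000/8,000 generations,
μ = 10⁻⁸; IM migration defaults are low (within-locality 5×10⁻⁶,
between-locality 5×10⁻⁷ — 4Nm well under 1), consistent with the very low
gene flow the system's demographic analyses support.

## Problem sizes and numerical choices

Desk-scale defaults: 2,000 genes (the full-data scale of ~16,000 is a
config choice away), ~5,000 loci, 6 haploids per deme, 1,000–2,000
Monte-Carlo genealogies per likelihood evaluation (20,000 for standalone
expected spectra; the full-study scale of 200,000 is reachable through the
same knob). Model-selection validation uses 20 replicate datasets per
generating class with the generating topology required to win ΔAIC in at
least 70% of replicates. All stochastic operations take explicit seeds;
the pipeline derives per-stage seeds from one master seed and re-running an
unchanged config reproduces outputs byte-for-byte.

Known limitations: no recombination within loci and free recombination
between them; no linked selection; composite-likelihood ΔAIC is used for
ranking only (no bootstrap CIs — the 10-best-runs interval heuristic used
with such pipelines is not a calibrated CI and is not implemented); the
k-way intersection test assumes independent uniform draws within a fixed
background; cRDA treats samples as exchangeable within pair blocks.
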