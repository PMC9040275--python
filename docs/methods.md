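# Methods

## The model

The framework treats the per-gene count of damaging de novo mutations in a
trio cohort as Poisson: if a gene's de novo rate for a variant class is μ
per individual per generation, the expected count in N trios is λ = μN, and
sums over cohorts and variant classes remain Poisson with summed means.
Enrichment is the upper-tail probability P(X ≥ observed | Poisson(λ)).
Everything else in the package exists to supply the λ's (the two rate
models), to justify them (the drift simulator), or to interpret the hits
(gene-set statistics and the prioritizer).

### CNV rate model

The deletion-rate model rests on the Watterson relation: for neutral,
unlinked variation at mutation–drift equilibrium, the expected number of
segregating sites in a sample of n alleles is a_{n−1}·4Nₑμ with
a_k = Σᵢ₌₁ᵏ 1/i.  Per-gene site counts in a population SV catalog are
therefore proportional to per-gene mutation rates *where selection can be
ignored*.  Training genes are chosen to make that assumption defensible:
autosomal, LOF-tolerant (LOEUF at or above the first-decile cutoff 0.278),
and with no LOF-intolerant gene inside a 1 Mb flank on either side, so that
a deletion extending beyond the gene is unlikely to remove constrained
sequence.  The approach cannot see selection on noncoding elements inside
the windows; that is a known limitation of the training-gene definition,
not of the implementation.

Counts of exon-deleting deletion sites (any overlap length ≥ 1 bp; sizes
50 bp – 1 Mb inclusive) are regressed on five covariates.  The regression
family is binomial by default: gene g's count is Binomial(N, p_g) with N
the total qualifying site count over the training genes and a logit link —
the counts are literally a partition of a fixed catalog.  A log-link
Poisson family is available (`family="poisson"`); for the small p involved
the two agree closely, and the binomial-logit slopes estimate the
log-linear coefficients of the generating law.  All 31 nonempty covariate
subsets are fitted; the lowest AIC wins, ties broken toward fewer
covariates.  Predicted training totals equal observed totals exactly
(canonical-link mean preservation), which the absolutization step relies
on.

Absolutization multiplies the per-gene relative rates by
(total absolute training rate) × (mean training genes hit per CNV site) /
(total relative training rate).  The total absolute rate comes from the
Watterson estimator evaluated per catalog population and averaged without
weighting; Nₑ and the sampled allele count are required inputs with no
default, since they are properties of the catalog, not of the method.
The genes-per-CNV factor corrects for one deletion event being counted
once per overlapped gene.

Covariate conventions: telomere distance is the minimum of the distances
from the two gene boundaries to the chromosome ends, capped at 25 Mb
(site counts are flat beyond that range); SD pairs count pairs on the
gene's chromosome with members < 1 Mb apart and at least one member within
the gene body ± 1 Mb (the window is configurable); the SD count enters
linearly (a log1p transform is a caller-side option since the covariate
table is a plain DataFrame).  Cohort-level de novo CNV calls above 1 Mb
are excluded from observed counts (`filter_large_dncnvs`), mirroring the
rate model's upper size bound.

### Drift simulator

`drift_sim` is an allele-frequency-vector Wright–Fisher simulation: each
of n_sites independent biallelic sites starts monomorphic ancestral,
mutates symmetrically in both directions at site_mu per allele copy per
generation, and is resampled binomially each generation.  Sampling at the
end is hypergeometric (without replacement) from the 2N allele pool; a
site counts as segregating when the sample is polymorphic (a flag switches
to "any derived allele").  The frequency-vector formulation is
statistically identical to an individual-based run for unlinked neutral
sites and is what makes desk-scale grids feasible.

The reference configuration (Nₑ = 100,000; 10⁶ generations; 10,000
sampled individuals; 100/320/1000 sites at 10⁻¹⁰–10⁻⁷ per site; ≥ 300
replicates) is the default `DriftConfig`.  Tests and the acceptance run
use a scaled-down configuration chosen so that the closed form it is
checked against is actually valid there: Nₑ = 1000 with 20,000 (= 20·Nₑ)
generations of burn-in, a 100-individual sample (sample fraction 0.1 —
at larger fractions the Kingman-coalescent expectation visibly
underestimates Wright–Fisher sampling), and per-site θ·a_{n−1} ≈ 0.07
(the a·θ formula is first-order in θ; at θ·a ≈ 0.3 saturation already
depresses polymorphism by ~10%).  Under these conditions the simulated
mean matches a_{n−1}·4Nₑμ_total to a few percent, and a 3 × 3 grid of
(sites × rate) gives a rate↔count Pearson correlation above 0.99.

### SNV/indel rates

Class rates per gene are sums of per-possible-variant trinucleotide-model
rates.  Damaging missense (d-MIS) is the sum restricted to variants with
MPC > 2; genes whose missense variants carry no MPC annotation get no
d-MIS rate and are burden-tested once (LOF only).  Splice acceptor/donor
rates are taken from the per-variant list when present, else 0.
Frameshift = 1.1 × nonsense (the frameshift:nonsense ratio observed in
large exome DNM data; configurable), and LOF-SNV = nonsense + splice +
frameshift.  Cohorts with per-base depth use the piecewise depth
adjustment rate × 0.025·depth for depth < 40 (continuous at 40, never
increasing a rate); cohorts without depth are instead rescaled by their
rare-synonymous observed/expected ratio, which forces expected synonymous
counts to match observed by construction.  The calibration multiplier is
applied to the SNV/indel classes only: the CNV-LOF column comes from the
deletion model, whose absolutization already anchors it to observed data.

### Burden testing and correction

Three tests per gene where d-MIS is defined (LOF; d-MIS; LOF + d-MIS),
one otherwise.  The default correction is two-step: within-gene Bonferroni
(n_tests × min p, capped at 1) then BH across genes, significant at
q < 0.05; a flat mode compares every individual test against
α/(n_genes × 3).  Significant genes absent from a curated known-gene list
are "new"; a new gene is "plausible" if LOF-enriched with pLI > 0.9 and
LOEUF < 0.35, or d-MIS-enriched with missense z > 2.5 or ≥ 2 d-MIS DNMs at
one amino-acid position.  The thresholds are module constants because they
are part of the classification rule, not free parameters; judgment-call
exceptions (small genes with low o/e but modest pLI) are deliberately not
automated and enter through the manual exclusion/inclusion lists.

### Gene-set statistics

One-tailed Fisher exact and the hypergeometric upper tail are the same
number under fixed margins; both are exposed because source analyses name
either.  The testing universe is the set of genes carrying the relevant
annotation, supplied by the caller — results are only comparable given the
same universe.  GO-style set-size filtering (20–500 members within the
universe) is applied on request.  Empirical term-count p-values redraw the
target set uniformly from the universe and re-test at the same q
threshold; the 1/n_draws resolution floor is reported alongside.  The
term-similarity coefficient is the equal-weight mean of Jaccard and
overlap coefficients, with graph edges above 0.375 (PPI-cluster maps) or
0.5 (GO maps).

### Prioritizer

Predictors: pLI, LOEUF, missense z, CDS length, brain-coordinate count and
GO-term count (integers), two binaries (brain-specific expression,
enriched-PPI-cluster membership), and the co-expression module as a
five-level categorical (the four known-gene-enriched modules and Others).
Numeric predictors are standardized with training-set statistics; the
module is one-hot encoded, so the input width is the encoded feature count
(13) rather than the nominal predictor count.  Missing brain-coordinate
counts impute to 1 (the candidate-set median in the reference analysis)
and missing modules to Others; genes missing any core constraint metric
are dropped from training and rejected at scoring.

The network is a scikit-learn `MLPClassifier`: two 128-unit ReLU hidden
layers, logistic output, Adam, log-loss (binary cross-entropy), batch
size 5, 5 epochs with per-epoch shuffling under the run seed, no L2
penalty.  Retraining distributions (for AUC empirical p-values and
median-of-models posteriors) derive per-model seeds deterministically from
the run seed.  Likelihood ratios divide Gaussian-KDE densities
(Scott's-rule bandwidth, configurable) of positive-control and
negative-control score distributions, floored at 1e-12 before division;
the naive-Bayes posterior is prior·LR/(prior·LR + 1 − prior), which
returns the prior exactly at LR = 1.

## Synthetic data: what it does and does not emulate

`make_genome` lays non-overlapping genes with log-normal lengths and exon
counts on a few ~100 Mb chromosomes, clusters LOF-intolerant genes so the
training-gene flanking rule excludes real neighbours, and emits matching
constraint tables and SD pairs.  `make_sv_catalog` draws per-gene site
counts Poisson around exp(β·x) for a known β and places each site across a
random exon of its gene.  `make_dnm_cohort` draws class counts Poisson at
fold × rate × trios with realistic per-gene rate scales (synonymous
≈ 10⁻⁵, CNV-LOF ≈ 10⁻⁶) and supports spiked genes and forced recurrent
codons.  `make_predictor_table` produces class-conditional Gaussian /
Bernoulli / categorical predictors whose separation parameter smoothly
interpolates between exchangeable classes and near-separable ones.

Passing tests on these fixtures show that the estimators recover known
generating processes and control their error rates under the stated model.
They do not show robustness to what real data add: annotation error,
cryptic relatedness, calling artifacts correlated with covariates,
selection leaking into "neutral" regions, or predictor distributions far
from Gaussian.  Those require real-cohort validation.

## Problem sizes and numerical choices

The test and acceptance runs use, as the package's standard desk-scale
configurations: 2,000 training genes / 4,000 sites for coefficient
recovery (binomial-logit slopes within 10% of the generating law); 800
genes × 50 replicate catalogs of 1,600 sites for AIC selection
consistency; 300-gene cohorts at the merged-cohort scale of 41,165 trios
with 20 replicates for null FDR and 10× spike power (spiked genes are
large genes, per-class λ ≈ 0.8, as real NDD hits are — an analytic
Poisson-tail calculation shows BH at 300 genes needs combined observed
counts around 9); and 120/480-gene predictor tables at separation 3 for
the network.  GLM non-convergence marks a candidate model failed and
excludes it from selection; an intercept column is always added even when
a covariate is constant (the pseudoinverse handles the collinearity).
Degenerate inputs raise rather than warn: all-zero counts, empty
universes, single-class labels, degenerate simulation grids.

## Known limitations

- The binomial reading of the site-count regression ignores
  overdispersion; a quasi-likelihood or negative-binomial family would be
  the next step for real catalogs.
- The drift simulator is strictly neutral, constant-size and unlinked; it
  justifies the rate model's premise but cannot probe demography or
  background selection.
- The plausibility rules encode fixed constraint thresholds; genes like
  small, highly depleted genes with modest pLI will be missed unless
  manually included.
- Watterson absolutization needs externally supplied Nₑ and allele counts
  per population; uncertainty in Nₑ propagates linearly into absolute (not
  relative) rates.
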