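# Methods

`cryptevolve` analyses somatic mutations in colonic crypts — monoclonal
epithelial units of ~2,000 cells whose whole-genome variants approximate a
single lineage's history. The pipeline runs from per-crypt read counts at
candidate variant sites to disease-duration effects on mutation rates, and
ships a synthetic cohort generator that reproduces the statistical structure
of such a study together with ground truth for every stage.

## Variant classification

For each patient, candidate sites carry per-crypt variant (`k`) and total
(`n`) read counts.

**Germline test.** A heterozygous germline variant is present in every crypt
at VAF 0.5. Counts are pooled over all crypts and the one-sided exact
binomial p-value `P(X <= sum k | X ~ Bin(sum n, p0))` is computed with
`p0 = 0.5`, or `0.95` on the X/Y of males (hemizygous dosage with residual
noise; the female X is treated as an autosome). p-values are BH-corrected
within the patient, SNVs and indels as separate families (configurable). A
site is a somatic candidate at `q < 1e-3`, relaxed to `q < 1e-2` when fewer
than five crypts were dissected — with few crypts, pooled counts cannot
separate the hypotheses as sharply.

**Overdispersion filter.** Somatic variants show presence/absence structure
across crypts; artifacts scatter binomially. Candidates are fitted with a
beta-binomial parameterized by mean `mu` and intra-class correlation `rho`
(shapes `mu(1-rho)/rho`, `(1-mu)(1-rho)/rho`). `rho` is maximized over 100
log-spaced grid points on `[1e-6, 10^-0.05]`, profiling `mu` per grid point
by golden-section search on (0, 1), vectorized across the grid; the grid
resolution and the profile tolerance (1e-6) are implementation choices, the
range and the decision threshold are not: `rho < 0.1` means artifact.

**Read support.** Sites where no crypt reaches 3 variant reads at depth 5
are `low_support`; this is decided before the dispersion test, which is
unidentifiable from 1–2 stray reads. Classes are therefore disjoint:
germline / somatic / artifact / low_support.

An optional matched-normal pre-step removes sites with germline-like support
(>= 3 reads at VAF >= 0.2) in a designated non-epithelial sample.

## Branch assignment

Crypt phylogenies are inputs (rooted Newick; tree inference is out of
scope). A somatic mutation on branch `b` is carried by exactly the crypts
below `b`. Its placement likelihood is a product of binomials: carrier crypt
`c` has success probability equal to its clonality estimate `v_c`, all
others the sequencing error rate (default 1e-3). The mutation goes to the
maximum-likelihood branch; ties from missing data resolve toward the more
recent branch. An adherence test compares the best branch against the best
*unconstrained* crypt subset: the likelihood-ratio statistic is referred to
chi-square with 1 df (a parametric-bootstrap null is available), and
mutations with `p < 0.01` are rejected as inconsistent with the tree. The
chi-square reference is a pragmatic choice — the free subset is selected,
not a single nested parameter — and behaves conservatively in calibration
tests (observed rejection under matched truth trees is ~1%).

## Clonality and detection sensitivity

Crypt clonality (the true median VAF of clonal heterozygous variants, < 0.5
through stromal contamination and unswept recent mutations) is estimated by
a truncated binomial fit: variant reads below the calling threshold are
never observed, so the likelihood of `k_i` at depth `n_i` is conditioned on
detection, `Bin(k_i | n_i, v) / P(K >= t | n_i, v)`. The truncation bound
`t = 3` variant reads matches this pipeline's own support filter
(configurable to 4 for callers that require 4); `v` is maximized on
(0, 0.5]. Crypts with fewer than 10 usable sites fall back to a cohort
default of 0.44 with a warning.

Per-crypt sensitivity is `Ss = P(mutant reads >= 4)` where mutant reads are
`Binomial(Poisson(lambda), v)` — equivalently `Poisson(lambda * v)` — with
`lambda` the crypt's median coverage. The closed-form Poisson tail is the
default; a Monte-Carlo mode with 100,000 simulated call attempts reproduces
the sampling-based procedure and agrees within Monte-Carlo error. Branch
sensitivity over `n` daughter crypts is `Sb = 1 - prod_i (1 - Ss_i)`, and
adjusted branch counts are `observed / Sb`, so single-crypt clones are
augmented more than multi-crypt clades. Per-crypt adjusted burdens are
root-to-leaf path sums. An independent estimate of per-call sensitivity
from duplicate dissections is `S = 2 n2 / (n1 + 2 n2)` (n2 called in both
replicates, n1 in exactly one); it is a lower bound because replicate
coverage is uneven.

## Signature attribution

SNVs map to 96 trinucleotide-context channels on the pyrimidine strand.
Branches with more than 50 mutations are treated as samples. Exposures to a
fixed reference signature matrix are fitted by multinomial EM with the
multiplicative update (uniform initialization, tol 1e-8 on the relative
log-likelihood change, max 10,000 iterations); the log-likelihood is
non-decreasing by construction and is asserted in tests. Fitted exposures
are *reconstituted*: signatures explaining <= 10% of mutations are dropped
(smallest first) and the survivors refitted, iterating until stable —
guarding against overfitting correlated flat signatures. External spectrum
components are matched to references by cosine similarity with a 0.95
cutoff; matches to SBS40 are reported as SBS5 since both are flat and
practically indistinguishable. Crypt-level signature burdens are path sums
of branch exposures; branches below the 50-mutation cutoff either inherit
the nearest fitted ancestor's proportions (default) or contribute their
count as unassigned — both options are exposed because the aggregation rule
for small branches is genuinely open.

## Burden models

Adjusted burdens are modelled with a linear mixed model mirroring the
sampling design:

* fixed effects for age and disease duration (optionally colon location as
  treatment-coded dummies with proximal reference, coverage, smoking
  duration, driver count), all in mutations/crypt/year;
* **no intercept** — embryonic mutations are filtered with the germline, so
  expected burden at birth is zero;
* nested random deviations for patient and biopsy-within-patient with
  *separate variance parameters per cohort*, encoded as variance components
  on cohort indicator designs; the residual variance is shared. The model is
  fitted by maximum likelihood (not REML) so nested fits are comparable by
  likelihood-ratio tests. Disease duration is zero for controls and for
  never-inflamed biopsies of cases.

The duration effect is tested by an LRT against the model without the term
(chi-square, 1 df). Cohort differences in patient- or biopsy-level SDs are
tested by LRTs comparing cohort-specific against pooled variance parameters,
one level at a time; equality of two variances is an interior hypothesis, so
the chi-square reference applies. The random-effect placement (additive
deviations rather than random slopes) was chosen to match variance
components reported in mutation units; a slope parameterization would report
per-year SDs instead.

Structural-variant counts are few, so they use a mixed Poisson regression
with mean **linear in disease duration** (`rate * duration`): the
coefficient is directly an events/crypt/year rate and its reciprocal the
years per event. A patient-level log-normal frailty is integrated out by
25-node Gauss-Hermite quadrature; with the frailty off and no baseline the
ML estimate reduces to `sum(counts)/sum(durations)`. The duration LRT uses a
baseline-augmented nesting (`mean = b0` vs `b0 + rate*duration`) because the
pure zero-intercept null assigns probability zero to any nonzero count. A
log-link alternative would report a rate ratio instead; the identity link
was chosen so the coefficient is on the reported scale.

## Synthetic cohorts

The generator emulates nested patient → biopsy → crypt sampling. Defaults
encode the study-scale conditions: 40 case + 40 control patients, 2 biopsies
of 5 crypts, ages uniform on 20–75 y, disease durations uniform on 1–30 y
(zero for controls and for a configurable 10% never-inflamed fraction of
case biopsies), substitution rates of 40/crypt/year of age and 55/crypt/year
of disease, indel rates 1.0 and 6.8, CNVs at 0.067/crypt/year of disease,
patient-level SDs 776 (cases) and 383 (controls) substitutions with
biopsy-level 955 and 407 (indels: 80/34 and 81/18), median coverage 18.2x,
and crypt clonality uniform on 0.38–0.50 (centre 0.44).

Each patient gets a random bifurcating genealogy: within-biopsy
coalescent-style merges uniform in molecular time, biopsy subtrees joined
during a short developmental epoch (first 5% of molecular time), and a clade
spanning two biopsies with probability 1/19 — crypt fission timing has no
established generative model, so this is an implementation choice, not a
reproduction. Branch mutation counts are Poisson at clock rates over each
branch's epoch using the descendant-average mean; terminal branches absorb
the remainder so path sums hit each crypt's mean burden exactly in
expectation.

Patient and biopsy deviations are **mean-one lognormal factors** calibrated
so the deviation SD at the cohort's reference burden equals the configured
SD in mutation units. Additive zero-mean Gaussian deviations would need
clipping at zero, which lifts cohort means and — in a zero-intercept model
where duration is the only case-specific covariate — biases the duration
effect upward by ~10%; the multiplicative form keeps
`E[burden | age, duration]` exactly on the linear predictor and burdens
nonnegative. The per-crypt driver offset stays outside the factor: a shared
multiplicative factor on a crypt-varying covariate creates biopsy-varying
slopes whose precision weighting attenuates the pooled estimate.

Read-count matrices (optional; burden-only mode skips them) place germline
sites in every crypt at VAF 0.5 (0.95 on the male X), somatic sites at the
crypt's clonality in carrier crypts only, and artifact sites as
beta-binomial scatter with mean VAF 0.05 and rho 0.01; depths are Poisson
around the crypt's median coverage. Branch spectra, when signature rates are
configured, split each branch's substitutions into age- and
disease-attributed parts and draw channel counts from well-separated
synthetic reference signatures (block-structured, generated by code and
labelled synthetic — they stand in for external reference matrices, which
are inputs, not outputs, of this package).

What the generator does **not** emulate: read-level errors and mapping
artifacts (only count-level noise), episodic mutational pulses (rates are
linear in time), spatial structure of crypt fission, indel-channel spectra
(indel counts are totals only), and real reference signatures' correlated
flat profiles. Passing recovery tests therefore demonstrate that the
estimators are calibrated for the assumed data-generating structure, not
that the structure is the true one for any particular dataset.

## Problem sizes and runtime choices

Recovery experiments use 80 patients x 10 crypts per replicate and report
medians over 20 replicates in the acceptance script (5 replicates in the
test suite); calibration tests for type-I error and CI coverage use 200
replicates of a 24-patient design generated exactly under the fitted model.
Degenerate inputs are handled explicitly: zero-depth sites are low_support,
single-crypt sites leave rho at the grid boundary and are flagged
degenerate, empty branches adjust to zero, all-zero spectra give zero
exposures, and non-converged mixed models are reported with a warning flag
rather than silently dropped.
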