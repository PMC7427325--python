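# cryptevolve

Somatic evolution of the colonic epithelium, one crypt at a time.

Colonic crypts are monoclonal units, so deep whole-genome sequencing of
laser-captured crypts reads out the mutational history of single epithelial
lineages. In chronic inflammation (inflammatory bowel disease), the question
is whether and how fast disease accelerates that history. `cryptevolve`
implements the crypt-level analysis required to answer it:

1. **Variant filtering** — classify candidate sites per patient as germline,
   somatic, artifact or low-support using a pooled one-sided exact binomial
   test against the germline VAF (null p₀ = 0.5, or 0.95 on the male X/Y),
   BH correction (somatic at q < 10⁻³), a beta-binomial overdispersion grid
   ML (artifact when ρ̂ < 0.1), and read-support thresholds (≥3 variant
   reads, depth ≥5).
2. **Phylogeny branch assignment** — place each somatic mutation on a branch
   of the patient's rooted crypt tree by maximum likelihood over binomial
   read counts, rejecting non-tree patterns at p < 0.01.
3. **Sensitivity adjustment** — estimate each crypt's clonality v by a
   truncated-binomial fit to its VAF distribution, convert to detection
   sensitivity Ss = P(Poisson(λ·v) ≥ 4), combine over a branch's daughter
   crypts as S_b = 1 − ∏ᵢ(1 − Ss,ᵢ), and adjust branch counts to
   observed / S_b.
4. **Signature attribution** — build 96-channel spectra for branches with
   >50 mutations, fit nonnegative exposures to reference signatures by
   multinomial EM, refit on signatures explaining >10% of mutations, and
   match components by cosine similarity (≥0.95; SBS40 reported as SBS5).
5. **Burden models** — zero-intercept linear mixed models of per-crypt
   burden with fixed effects for age and disease duration (mutations per
   crypt per year) and nested patient/biopsy random deviations with
   cohort-specific variances, fitted by ML and compared by likelihood-ratio
   tests; structural-variant counts use a mixed Poisson model with mean
   rate × duration.
6. **Synthetic cohorts** — a first-class generator that reproduces the
   nested sampling design, trees, read counts and clinical covariates, with
   ground truth for every stage.

The audience is groups analysing multi-sample clonal-unit sequencing
(crypts, glands, endometrial or bronchial units) who need a tested,
end-to-end reference implementation of this class of analysis.

## Worked example

Simulate a small cohort, run the full pipeline, and fit the burden model:

```bash
cryptevolve simulate --out simdir --seed 7          # writes matrices, trees, meta
cryptevolve run-all --in-dir simdir --out rundir    # filter → assign → adjust → fit
```

or from Python:

```python
import cryptevolve as ce

cfg = ce.CohortConfig(seed=1)                  # study-scale defaults
_, meta, truth = ce.simulate_cohort(cfg, genotypes=False)
df = ce.burden_table(meta, truth)
fit = ce.fit_burden_lmm(df, response="subs_burden",
                        fixed=("age", "disease_duration"))
print(fit.coef.loc[["age", "disease_duration"], ["estimate", "lo", "hi"]])
```

which prints (seed 1):

```
                   estimate         lo         hi
age               41.756070  38.175626  45.336515
disease_duration  51.790615  33.813024  69.768206
```

The cohort was generated with 40 substitutions/crypt/year of age and 55 per
year of disease duration; the fitted coefficients recover both within their
Wald 95% intervals, i.e. the model separates normal ageing from the
disease-associated excess despite nested correlation and cohort-specific
variance structure. `ce.fit_sv_rate(df)` likewise recovers the generating
CNV rate (0.067/crypt/year ≈ one event per 14.9 years of disease).

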