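# Methods

## Scope and model

`snpmeta` pools case-control association evidence for a biallelic SNP
across k independent studies. The unit of input is one study's
genotype counts per arm; all inference is on the odds-ratio scale.
Assumptions: studies are independent; within a study, genotype counts
are multinomial; the log odds ratio is approximately normal with
variance estimated by Woolf's formula (1/a + 1/b + 1/c + 1/d); under
random effects, true study log odds ratios are exchangeable
N(θ, τ²) draws.

## Genetic-model contrasts

Each record maps to a 2×2 table under five contrasts (exposure =
effect-allele category): allele (per-allele counts, table total
2× subjects), homozygote (hom-alt vs hom-ref, heterozygotes removed),
heterozygote (het vs hom-ref, hom-alt removed), dominant (carriers vs
hom-ref), recessive (hom-alt vs all others). The allele model treats
the two alleles of one subject as independent — standard practice,
exactly correct only under HWE. Effect-allele orientation is taken
from the record's `effect_allele` column, never inferred from
frequency, so a file with flipped labels cannot silently invert the
pooled OR. Reported case/control sample sizes are always full subject
counts, including for the homozygote/heterozygote models whose tables
exclude a genotype class — matching how published summary tables
print totals.

## HWE screening

Controls are screened with the 1-df Pearson chi-square against
expected proportions {(1−p̂)², 2p̂(1−p̂), p̂²} at the sample allele
frequency. No continuity correction and no exact test: the screened
literature reports the χ² form, and at the control-arm sizes this
package targets (hundreds per arm) the asymptotic test is well
calibrated (verified by simulation at N = 500: rejection rate 0.05 ±
0.02 over 2000 replicates). Monomorphic arms return χ² = 0, p = 1 by
convention. The default exclusion alpha is 0.05, configurable;
filtering applies to controls only. An exact (enumeration) HWE test
is a possible extension, not implemented.

## Pooling and model selection

Per-study effects use the Haldane-Anscombe correction: +0.5 on all
four cells of any table containing a zero (flagged on the effect).
A table with two or more empty margins is rejected as uninformative.

The fixed-effect estimate is Mantel-Haenszel,
OR_MH = Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ), with **no** correction inside the sums
(zero cells contribute zero terms), and the Robins-Breslow-Greenland
variance for its log — the sparse-data-safe choice used by mainstream
meta-analysis software. Cochran's Q is computed with inverse-variance
weights about the inverse-variance fixed-effect mean even though the
reported fixed estimate is MH: that is the form the DerSimonian-Laird
moment estimator is derived from, and the universal convention.
I² = max(0, (Q−df)/Q)·100. τ² = max(0, (Q−df)/(Σw−Σw²/Σw)).

Selection rule: fixed effect iff p(Q) > 0.05 and I² < 50%; otherwise
random effects, i.e. inverse-variance pooling with weights
1/(vᵢ + τ²) (the Stata-metan-era default). Association tests are
two-sided normal: z = |ln OR|/se, CI = exp(ln OR ± z₀.₉₇₅·se). k = 1
conventions: Q = 0, df = 0, p_het = 1, I² = 0, fixed effect; a single
study with a zero cell is reported via its corrected effect, since
uncorrected MH is degenerate there.

## Publication bias and sensitivity

Begg-Mazumdar: effects are standardized against the fixed-effect mean,
tᵢ = (θᵢ − θ̂)/√(vᵢ − v̂) with v̂ = 1/Σw; Kendall's S between tᵢ and vᵢ
is normalized by the tie-corrected variance (k(k−1)(2k+5)/18 minus tie
terms); no continuity correction by default (matching the era's Stata
`metabias` default), with the corrected variant behind a flag. If tie
correction drives the variance to zero (all standardized effects
equal) the statistic is defined as z = 0, p = 1.

Egger: OLS of θᵢ/seᵢ on 1/seᵢ; intercept, its standard error, and a
t test with k − 2 df. An exact fit (zero residual) returns p = 0 for
a nonzero intercept. Both tests require k ≥ 3 and always consume
per-study corrected inverse-variance effects, independent of which
estimator produced the headline pool. Both tests are anticonservative
under strong between-study heterogeneity (measured ≈7% type-I for
Begg at α = 0.05 with τ = 0.12, k = 17); no heterogeneity-robust
variant is implemented.

Leave-one-out re-runs the full pooling (including re-selection of
fixed vs random) on each k−1 subset and reports the pooled-OR range
across omissions.

## Synthetic corpora

The generator draws, per study: arm sizes uniform on configured
integer ranges (defaults 100–1500, the span typical of candidate-gene
case-control studies); a control effect-allele frequency uniform on a
configured sub-interval of (0,1) (default 0.15–0.45); a study log OR
θᵢ = ln(OR) + N(0, τ²); the case allele frequency by the odds
transform p′ = p·e^θ/(1−p+p·e^θ); and multinomial genotype counts
from HWE proportions at each arm's frequency. The effect is therefore
multiplicative per allele; genotype-model ORs are induced, not
independently configurable — a one-parameter generator matching the
allele-model headline analyses. Optional HWE violation converts a
fraction of expected heterozygotes in designated control arms into
homozygote pairs (allele counts preserved, excess homozygosity
injected). Subgroup labels default to round-robin assignment.
Everything is deterministic under the seed.

What the generator does **not** emulate: genotyping error, covariate
confounding, linkage disequilibrium with causal variants, non-HWE
case arms beyond the allele-model effect, or study-level quality
differences. Passing calibration tests on these corpora therefore
demonstrates correctness of the estimators under their own sampling
assumptions, not robustness to real-literature pathologies.

Two frozen corpora (`paper_like_fixture`) mirror the shape of the
published *CYP4F2* meta-analysis: rs1558139 — 10 Asian studies, 3462
cases/3547 controls, hypertension/CAD/IS mix, 8 population-based,
OR 0.92, τ = 0; rs2108622 — 17 studies, 10213/8033, 15 Asian, 12
population-based, OR 0.95, τ = 0.12 (the published analysis showed
substantial heterogeneity). Per-study arm sizes are fixed partitions
chosen so every published subgroup margin (k, cases, controls) is
matched exactly; genotype splits are seeded HWE draws (controls
redrawn until HWE p > 0.2), with no claim of study-level fidelity to
the real corpus. Fixture seeds are the rs numbers.

## Numerical and design choices

- Thresholds (CI level 0.95, heterogeneity p 0.05, I² 50%, continuity
  0.5, HWE alpha 0.05) live in `MetaConfig`; all are the conventional
  defaults of the field.
- Pooling is permutation-invariant by construction; TSV/JSON report
  output is byte-deterministic for identical inputs.
- The published-rows consistency checker (`z_from_or_ci`) assumes
  log-symmetric CIs; checks against 2-decimal published tables must
  use interval arithmetic on the rounding slack (±0.005 per printed
  number), as the acceptance tests do. Two published rows are
  internally inconsistent beyond rounding (point estimate outside its
  own CI, and a duplicated CI with conflicting z) and are flagged
  `consistent=False` in `snpmeta.published`.
- Validation problem sizes (e.g. 200 replicates for parameter
  recovery, 500 for bias-test calibration, 2- and 3-study table
  enumeration/sampling for the MH oracle) were chosen to keep
  Monte-Carlo error well inside the asserted tolerances while the
  whole suite runs in seconds.

## Known limitations

- No REML/Paule-Mandel τ², Peto OR, meta-regression, trim-and-fill,
  or exact HWE test (out of scope by design).
- The allele model's subject-to-allele doubling ignores within-person
  allele correlation when HWE fails.
- Begg/Egger miscalibration under large τ (above) means a chance
  rejection on a single heterogeneous corpus is expected occasionally
  even absent any small-study effect.
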