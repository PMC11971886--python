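# Methods

## Scope and model

`cismr` implements a two-sample summary-statistics causal screen of many
quantitative exposures (plasma proteins, measured in SD units) against one
binary outcome (a disease endpoint on the log-odds scale), in the order:
forward MR over the whole panel → Benjamini–Hochberg FDR → Bayesian
colocalization of the FDR survivors → reverse MR → lifestyle-exposure MR.
Later stages only ever see the survivors of earlier ones; the FDR family
is exactly the set of exposures that yielded at least one harmonized
instrument, and skipped exposures are logged with the reason.

The identifying assumptions are the usual instrumental-variable triple:
relevance (enforced by the significance and F filters), independence, and
exclusion. Restricting instruments to the cis region of the protein's own
gene is the design-level guard against horizontal pleiotropy; the
MR-Egger intercept (when ≥ 3 instruments exist) and Cochran's Q are
attached as sensitivity statistics but with 1–2 instruments per protein —
the regime this screen operates in — neither is informative, which is why
the headline estimator is fixed-effect IVW (a multiplicative
random-effects variance is not estimable from 1–2 ratios).

## Harmonization

Exposure and outcome records are matched by SNP id only (the synthetic
and single-build use case makes positional matching unnecessary).
Outcome records in swapped or complemented-swapped orientation have the
effect sign flipped and frequency complemented. A/T and C/G pairs are
strand-ambiguous: they are aligned by allele frequency when both traits
report one, and dropped as ambiguous when the effect-allele frequency is
within 0.08 of 0.5 or missing (a conventional MR default; configurable).
Indels and incompatible pairs are dropped. Harmonization is idempotent on
the kept set and invariant to wholesale orientation flips of the outcome
file; both properties are tested.

Record validation treats the p-value/effect consistency check on the z
scale (|β/se| vs the normal quantile of p/2, 10% relative): printed
p-values are rounded, and a relative tolerance on p itself diverges for
large z. Inconsistent rows are warned about, not dropped.

## Estimators

* **Wald ratio** (1 instrument): β̂ = β_out/β_exp with
  se² = (se_out² + β̂² se_exp²)/β_exp². The exposure-uncertainty term is
  kept deliberately: dropping it (the common first-order shortcut) makes
  CIs anti-conservative by a factor ≈ √(1+θ²) when the exposure GWAS is
  not much larger than the outcome GWAS — at θ = 0.8 and equal effective
  sample sizes, nominal 95% intervals would cover only ~87% of the time,
  outside this package's own 93–97% calibration requirement.
* **IVW** (k ≥ 2): precision-weighted mean of per-SNP ratios. The per-SNP
  ratio variances are computed in two passes, plugging a pooled
  first-pass estimate into the exposure term rather than each SNP's own
  noisy ratio: weighting by a SNP's own ratio correlates weights with
  ratios and attenuates the mean (this is the same estimator as the
  weighted regression of β_out on β_exp through the origin). Normal
  reference for p-values.
* **MR-Egger** (k ≥ 3): weights se_out⁻², instruments oriented to
  positive exposure effects; coefficient covariance (XᵀWX)⁻¹ without
  residual rescaling (fixed-effect convention, matching the IVW choice),
  normal reference. Below 3 instruments the result is flagged undefined,
  not raised.
* **Cochran's Q** about the IVW mean, χ²(k−1).
* **FDR**: Benjamini–Hochberg step-up (via statsmodels), the standard
  reading of "FDR correction" when no procedure is named.

Odds ratios are exp(β) per SD of exposure; `or_ci_to_p` inverts a printed
OR/CI row back to (z, p) for consistency checks and is the exact inverse
of `effect_to_or` (tested to 1e−10).

## Colocalization

Wakefield log approximate Bayes factors, log ABF = ½[log(1−r) + r z²]
with r = W/(V+W), V = se², use prior effect SD √W = 0.2 for quantitative
traits and 0.15 on the log-odds scale for case-control traits — the
established defaults of the published colocalization method this stage
reimplements; the source study states none of them, so they are surfaced
as configuration. Per-SNP priors default to p1 = p2 = 10⁻⁴, p12 = 10⁻⁵.
Hypothesis masses are accumulated by log-sum-exp; in a single-SNP region
the H3 cross term vanishes identically and is set to exactly zero. The
decision rule — colocalized iff PPH4 > 0.75 or PPH3 + PPH4 > 0.8 — is
applied once per analyzed region (the cis window of each FDR survivor);
the thresholds are configuration. Note a known property of the
single-causal-variant model: a region whose two shared instruments are
both strong can shift posterior mass from H4 to H3; the combined
PPH3 + PPH4 clause is what keeps such regions called colocalized.

## Synthetic data generator

`simulate_region` draws z-scores from their exact large-sample
distribution z ~ MVN(√n·R·b, R): R is the regional LD correlation matrix
(AR(1), closed-form Cholesky), b the joint causal-effect vector, and
marginal effects are R·b by construction. β = z/√n and se = 1/√n on the
standardized scale; binary traits use the effective sample size
n_eff = 4/(1/n_cases + 1/n_controls) with β read as log-odds. Generated
p-values are exactly consistent with |β/se| by construction. All
randomness flows from one integer seed through `SeedSequence` spawning.

Default study conditions mirror the emulated data sources: exposure GWAS
n = 35,559; outcome 11,755 cases / 441,978 controls (n_eff ≈ 45,800);
1–2 independent genome-wide-significant cis instruments per protein;
region of 200 SNPs at 2 kb spacing around a TSS at 1.5 Mb. Per-SD joint
instrument effects default to U(0.05, 0.12) (0.25–1.4% of protein
variance, z ≈ 9–23) and adjacent-SNP LD to r = 0.35 with geometric decay:
together these make r² < 0.1 clumping structurally recover exactly the
configured instruments — the SNP one step from a causal variant is
clumped away (r² ≈ 0.12) and the SNP two steps out carries too little of
the signal to reach 5×10⁻⁸. With slowly decaying LD (ρ = 0.9) instead,
"shadow" SNPs just outside the clump radius (r² ≈ 0.098) remain
genome-wide significant and a greedy r² < 0.1 clump returns ~6–7
"independent" instruments per region; real pQTL releases that report 1–2
instruments have evidently been pruned harder by the provider. The
region-pair `Scenario` used for colocalization benchmarks keeps ρ = 0.9
and a causal variance of ~1% (joint effect 0.1 at n = 10,000), where the
clumping question does not arise.

The study generator adds the outcome's own genome-wide loci on separate
chromosomes (independent, effects U(0.10, 0.25) log-odds) so the reverse
mode has instruments, and optional lifestyle traits with sub-genome-wide
instruments (|z| ~ U(4.8, 7) at n = 300,000, i.e. P between ~10⁻¹² and
~10⁻⁶) for the lifestyle preset. `reverse_theta` injects true
disease→protein effects (0 by default). A `flip_fraction` switch reverses
the reported orientation of outcome records to stress harmonization;
it is information-preserving and tested as such.

An instrument-level fast path (`draw_instrument_stats`,
`replicate_mr_estimates`) draws the same marginal distribution at the
instrument SNPs without building regions; the calibration suites use it
at 10,000 null MR tests (type-I error) and 500 replicates per θ ∈
{−0.5, 0, 0.3, 0.8} at n_exp = n_outcome = 50,000 (recovery and CI
coverage) — sizes chosen to put Monte-Carlo error well below the bands
being checked while the whole suite stays fast.

What the generator does **not** emulate: realistic human LD panels,
allele-frequency/effect-size coupling, assay measurement error or
batch structure, sample overlap between the two GWAS, population
stratification, and winner's-curse selection of instruments by the data
provider. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated sampling model, not robustness to
those real-data pathologies.

## Reverse and lifestyle modes

Reverse MR selects outcome instruments genome-wide (no cis window) with
the forward thresholds, zero LD across regions, and runs the same
estimator chain against each protein, with BH-FDR across the protein list
passed in (the coloc-validated set by default in `run_all`). A caveat the
synthetic experiments make explicit: when the forward effect is strong
enough that mediated cis SNPs reach genome-wide significance in the
outcome, genome-wide reverse selection picks them up and the reverse
estimate is contaminated toward 1/θ — the reverse-null expectation only
holds when the disease's own loci dominate its instrument set, as in the
emulated study. Lifestyle MR applies the lifestyle preset and reports
nominal p as the headline (mirroring the emulated analysis, which applies
no correction there), with a reference FDR column attached.

## Numerical choices and degenerate inputs

Two-sided normal p-values are floored at 1e−300 to stay in (0, 1] under
extreme z. Clumping breaks p ties lexicographically by SNP id, making the
output invariant to input row order. LD matrices are validated symmetric,
unit-diagonal and PSD within 1e−8. Empty harmonization intersections warn
and return empty rather than raising; a screen in which *no* exposure
yields instruments is an error carrying diagnostic counts. Report tables
contain no timestamps, so identical seeds give byte-identical runs.

## Known limitations

Single-causal-variant colocalization only (no conditioning or SuSiE-style
multi-signal decomposition); no weighted-median/mode or MR-PRESSO
estimators; no GWAS-VCF input, liftover, or reference-panel strand
inference; LD is taken as given per region, never estimated from
genotypes. These mirror the boundaries of the screen being reimplemented.
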