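# Methods

## Design and assumptions

The package implements two-sample summary-level Mendelian randomization:
per-variant associations with an exposure come from one study population and
associations with the outcome from a non-overlapping one, and the two are
combined only through effect sizes and standard errors. Validity rests on
the three instrumental-variable assumptions — each instrument is (1)
associated with the exposure, (2) independent of exposure-outcome
confounders, and (3) affects the outcome only through the exposure.
Assumption (1) is enforced empirically (significance filter, F statistics);
(2) and (3) cannot be verified from summary data, which is why the toolkit
couples every estimate to pleiotropy diagnostics (Egger intercept,
MR-PRESSO) and robust estimators (weighted median).

## Harmonization

Outcome effects are re-expressed on the exposure study's effect allele.
Allele swaps negate the outcome beta and complement its frequency; strand
flips (A/G reported as T/C) are resolved by complementing alleles before
comparison, which is safe for every non-palindromic pair. Palindromic
variants (A/T, C/G) carry no strand information in their alleles, so the
effect-allele frequency must disambiguate: inside the configurable window
(default eaf ∈ (0.42, 0.58)) — or when the frequency is missing — the
variant is dropped; outside it, outcome frequencies on the opposite side of
0.5 from the exposure's indicate opposite-strand coding and trigger a flip.
Allele pairs matching neither directly, swapped, nor after complementation
are dropped as mismatches. Duplicate variant ids keep the smallest exposure
p-value. Harmonization is idempotent on its retained output, and recoding
any variant on its other allele in both studies changes nothing downstream;
both properties are tested.

## Instrument selection and strength

Defaults follow standard practice for biobank-scale exposures: selection at
p < 5×10⁻⁸, greedy LD clumping at r² < 0.01 within a 10,000-kb window
(smallest p first; ties broken by lexicographic variant id so results do not
depend on input order). The LD matrix is supplied by the user or the
simulator — the package does not estimate LD from a reference panel. Pairs
farther apart than the window (when positions are available) are treated as
unlinked; without positions, every within-matrix pair is in-window.

Strength summaries: per-variant F = β²/σ²; per-variant
R² = β²/(β² + nσ²) (the 2·eaf·(1−eaf) heterozygosity factor cancels but the
function takes the GWAS-reported quantities); set-level R² is the sum over
the clumped (approximately independent) members; overall
F = ((n−k−1)/k)·(R²/(1−R²)), with a weak-instrument flag at F ≤ 10.

## Estimators

All weights are first-order: exposure-side uncertainty is ignored in the
IVW and Egger weights, the standard default of the field's tooling (IVW
offers a second-order switch). "Random effects" is the multiplicative
model: the fixed-effect SE is inflated by √max(1, Q/df), never deflated.
p-values come from the standard normal for IVW, Wald ratio and weighted
median, and from t on k−2 df for the Egger slope and intercept
(small-sample convention). The weighted-median SE is a parametric bootstrap
(default 1000 draws) resampling both βx and βy from their reported
sampling distributions, seeded for bit-reproducibility. Odds ratios and
95% CIs are exp(β ∓ 1.959964·σ). Two-sided p < 0.05 is flagged as
significant with no multiple-testing correction; the run manifest records
that convention explicitly.

MR-PRESSO: observed RSS = Σ w_j (βy_j − β̂₍₋ⱼ₎βx_j)² over leave-one-out IVW
fits with w = 1/σy²; the null distribution simulates βy* ~ N(β̂₍₋ⱼ₎βx_j, σy_j)
and βx* ~ N(βx_j, σx_j) and recomputes the RSS (default 5000 draws,
vectorized). The global p is (count+1)/(n_sim+1), so the smallest reportable
p is 1/(n_sim+1) — n_sim must comfortably exceed k/α for the
Bonferroni-adjusted outlier test to be able to flag anything, which is why
the default is 5000 rather than the 1000 minimum. The distortion test
compares the corrected-versus-uncorrected estimate shift against removals of
1000 random subsets of the same size. The corrected estimate is exactly the
random-effects IVW on the retained subset.

Multivariable MR regresses outcome effects on all exposures' effect columns
jointly (no intercept, weights 1/σy²), with SE inflation √max(1, Q/(n−K)).
The instrument set is the union of each exposure's selected, clumped
instruments, re-clumped jointly with the lead variant chosen by the best
p-value across exposures; all effects are aligned to the outcome study's
allele coding (roles-reversed harmonization) so the design matrix is
coherent across exposures. Exactly rank-deficient designs (e.g. an all-zero
exposure column) raise a collinearity error naming the offending columns;
the pipeline converts such errors into flagged rows and continues.

## Synthetic data generator

`simulate_pair` emulates the two-sample design directly on the summary
scale: continuous exposure in SD units from a biobank-sized cohort
(default n = 300,000), binary outcome on the log-odds scale from a
case-control consortium (default n = 280,000, case fraction 0.017,
matching a national-registry pancreatitis cohort's case-control ratio).
Standard errors are the large-sample forms 1/√(2p(1−p)n) and
1/√(2p(1−p)n·φ(1−φ)); exposure and outcome noise are independent (no
sample overlap). Defaults — 50 candidate variants, h² = 5%, MAF uniform on
(0.05, 0.5) — give per-variant F around 70–600, so the panel behaves like
an already-selected set of strong instruments. Effect magnitudes are drawn
uniform on (0.5, 1.5) with random signs and per-variant explained variance
equalized across MAF (larger effects at rarer alleles): plain Gaussian
effects would leave a tail of weak candidates, making "k strong
instruments" an ill-defined study condition. Only non-palindromic allele
pairs are drawn, so harmonization is lossless on simulated data; the
hand-written `fixture_small` covers the palindromic and mismatch branches
instead.

Horizontal pleiotropy adds a direct effect α_j to a configurable fraction
of variants: `balanced` is mean-zero Gaussian; `directional` is
positive-mean Gaussian **on the exposure-increasing allele** (sign tied to
the true exposure effect — with random allele coding a sign-free positive
mean would cancel under the orientation every estimator applies and produce
no directional bias at all); `inside_violating` makes α proportional to
instrument strength plus noise, breaking the InSIDE assumption MR-Egger
needs. The directional-robustness scenario used in validation fixes
`pleiotropy_frac = 0.3, pleiotropy_scale = 0.1` — gross direct effects whose
ratio-scale shift is roughly three times the causal effect.

What the generator does **not** emulate: LD-induced correlation between
nearby variants' effect estimates (the block LD matrix drives clumping
only), winner's-curse bias from selecting instruments in the same sample
that estimated them, population stratification, and sample overlap. Passing
calibration and recovery tests therefore demonstrates correctness of the
estimators under their own sampling model, not robustness to those
real-data pathologies.

## Validation problem sizes and numerical choices

Calibration uses 1000 replicates for the IVW null rejection rate and the
Egger-intercept type-I error, and 300 for the MR-PRESSO global test (whose
replicates each carry 1000 inner simulations); recovery uses 200 replicates
at θ = 0.3 and 100 planted-outlier seeds. Oracle equivalence checks IVW,
Egger and MVMR against an independent weighted-least-squares solver to
1e-10 relative error on 100 random fixtures. All randomness flows from
explicit seeds through named `numpy` generators; no global random state is
touched. Result tables serialize floats with `repr` (shortest round-trip),
making end-to-end reruns byte-identical at a fixed seed.

Degenerate inputs: single-instrument IVW falls back to the Wald ratio
(logged); estimators reject zero exposure betas, Egger rejects zero spread
in oriented exposure effects, and MR-PRESSO requires ≥ 4 instruments and
≥ 1000 simulations.

## Known limitations

Summary statistics only — no genotype-level input, liftover, or proxy-SNP
lookup. LD must be supplied; window semantics degrade gracefully without
positions. The multivariable instrument-union construction and the
frequency-based palindromic resolution are conventional choices, exposed as
configuration, not claims about any particular published analysis. The
weighted-median bootstrap SE is sampling-based and therefore only
reproducible at a fixed seed.
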