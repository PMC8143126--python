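# Methods

This note documents the models, estimators and numerical choices behind
`bovitherm`, what the synthetic-data generators do and do not emulate, and the
problem sizes the test suite uses.

## Snow-referenced albedo estimation

The estimator assumes the scene contains a fresh-snow surface whose albedo is
known (default `snow_ref = 0.85`, the standard fresh-snow value) and that
pixel brightness is, over the dynamic range of interest, proportional to
surface reflectance under common illumination. Under that assumption the
target/snow brightness ratio is an unbiased estimate of relative albedo, and
`albedo_abs = ratio × snow_ref`.

Choices and caveats:

* **RGB → gray.** The conversion rule is the unweighted channel mean, rounded
  half-up — the default of widely used image-analysis tools; ITU-R 601
  luminance weights are available via `gray_weights`. The choice matters only
  for colored (non-neutral) surfaces.
* **Ratios above 1** (target brighter than snow) are physically suspect but
  retained with a warning rather than clipped, so diagnostics can see them.
* **Masks are taken as given.** There is no automatic segmentation and no
  shadow correction; if shadowed snow pixels are included in the reference
  region the reference brightness drops and all albedos are inflated.
* **Quantization.** Images are 8-bit, so a patch rendered at
  `snow_gray × albedo / snow_ref` is rounded to an integer gray level; exact
  round-trip recovery of an injected albedo is possible only when that product
  is integral (the tests use such albedos). Otherwise the quantization error
  is at most `0.5/snow_gray × snow_ref` (≈ 0.002 at base gray 200).
* **Winter-only validity.** The method needs in-scene snow; it says nothing
  about summer coats, which differ in structure and reflectance.

Replicate summaries report the per-color mean and standard error `SD/√k`; with
one replicate the SE is undefined and returned as NaN.

## Albedo group comparison

Albedo is a proportion, so values are arcsine-transformed
(`arcsin(√p)`, the variance-stabilizing form) before the Shapiro–Wilk check.
Location is compared with Kruskal–Wallis (rank-based, hence invariant to the
monotone transform), and the ordered one-sided alternatives white > red,
red > black, white > black use **exact** Wilcoxon rank-sum p-values: with three
replicates per color the asymptotic approximation is meaningless, and the
smallest attainable one-sided p for 3 vs 3 is 1/20 = 0.05. Significance is
therefore declared at `p ≤ α` (not `<`), so full separation at the default
α = 0.05 is detectable at these replicate counts. Cohen's *d* uses the pooled-SD
formula on the raw albedo scale by default (configurable to the transformed
scale). Compact letters are connected components of the graph whose edges join
colors that are *not* significantly different; letters are assigned in
descending order of group mean.

## Synthetic winter scenes

`generate_winter_image` renders a uniform snow field (`snow_gray`, default
200) with non-overlapping rectangular patches at
`snow_gray × albedo / snow_ref`, then adds i.i.d. Gaussian pixel noise
(`noise_sd`, in gray levels) and rounds/clips to [0, 255]. The linear
brightness model is the unique one under which the ratio estimator is
unbiased, which is the point of the fixture. An optional `shadow_fraction`
darkens a random subset of snow pixels by 40% to emulate surface shadows.
Default patch albedos are the study-scale per-color values 0.69 / 0.16 / 0.04.
The generator does **not** produce photorealistic animal shapes, spatially
correlated noise, vignetting or mixed illumination — so passing tests show the
estimator inverts its own generative model, not that it is robust to real
photographic artifacts.

## Synthetic thermal observations

`generate_thermal_observations` draws `n` rows (default 638, split
white/red/black 183/158/297 by largest-remainder apportionment and shuffled).

**Covariates** are drawn through a Gaussian copula: correlated standard
normals (Cholesky factor of the declared correlation matrix; a non-PSD matrix
is rejected with a message) are mapped to uniforms and then through the
monotone power map `x = lo + (hi − lo) u^p` with
`p = (hi − lo)/(mean − lo) − 1`, which guarantees the marginal lies inside its
declared [lo, hi] range and has expectation equal to the declared mean. The
declared ranges are the study-scale ones (e.g. ambient temperature mean 4.4,
range −32.8…35.6 °C; KTClear mean 0.6, range 0.3…0.8). The four declared
high-correlation pairs (earth-skin temperature with each radiation flux,
humidity with wind, VPD with dewpoint) are set to 0.85 on the Gaussian scale —
comfortably above the 0.7 pruning threshold after the marginal maps — and the
implied LW/SW radiation entry is set to 0.6, which keeps the matrix positive
definite (it must exceed 2·0.85² − 1 = 0.445) while keeping that pair's sample
correlation safely below the pruning threshold, where the default
drop-preference list would otherwise be ambiguous. Each observation gets its
own synthetic day (`date_index` = row index); there are no weather time-series
dynamics and no repeated measures, matching the analysis's independence
assumption.

**Model mode** generates
`temp_cow = b0 + 0.1770·temp_amb + 19.172·ktclear − 27.026·albedo + ε`,
ε ~ N(0, `noise_sd`²) with `noise_sd` defaulting to 5 °C, and
`delta_t = temp_cow − temp_amb`. The intercept is not declared anywhere, so it
is calibrated once from the identity `E[temp_cow] = 32.4` at the declared
covariate means (proportion-weighted mean albedo 0.256), giving b0 ≈ 27.04.
A structural consequence used as a test: noise-free, regressing `delta_t` on
the same design shifts the ambient-temperature coefficient by exactly −1
(0.1770 → −0.8230) and leaves the others unchanged.

**Slope mode** generates `delta_t = a_c + m_c·temp_amb + ε` with per-color
slopes −0.45 / −0.92 / −1.07 and `noise_sd` defaulting to 3 °C; the per-color
intercepts are set so every color has E[ΔT] = 28.0 (the overall study-scale
mean) at the mean ambient temperature. This mode exists because the model-mode
design implies equal ΔT slopes across colors; slope-heterogeneity analyses
need a fixture in which the slopes genuinely differ.

All randomness in a generator call flows from its single integer seed
(`numpy.random.default_rng`); identical parameters and seed give bit-identical
output.

## ΔT, pruning and staged AICc selection

* **ΔT is signed** (`temp_cow − temp_amb`). Surface temperatures slightly
  below ambient occur (radiative cooling), and the negative per-color slopes
  only exist on the signed scale.
* **Pruning** compares only variables from the same data source (field /
  station / PRISM-like / satellite-like), flags |Pearson r| > 0.7, and drops
  the member of each flagged pair named in an explicit drop-preference list
  (default: earth-skin temperature, humidity, VPD). A flagged pair the list
  cannot resolve is an error demanding a rule — outcomes are configured, not
  guessed. Pruning is idempotent.
* **OLS fits** use an explicit numeric design matrix (intercept + terms);
  rank-deficient designs are rejected. Note the degenerate noise-free case:
  with zero residual noise `temp_cow` is an exact linear combination of the
  generating covariates, so the ΔT step-3 design containing `temp_cow` is
  rank-deficient by construction — a correct rejection, not a defect.
* **K convention**: intercept + slopes + residual variance, so null K = 2 and
  a one-predictor model K = 3. AICc requires n > K + 1. The Gaussian
  log-likelihood route agrees with the `n·ln(RSS/n)` closed form (tested).
* **Steps**: step 1 picks the best weather term ({ambient temperature,
  dewpoint, wind} by default — humidity is pruned before selection), step 2
  the best radiation term ({KTClear, LW, SW}), step 3 ranks the winners plus
  every subset of the animal attributes, each winner alone, and the null. A
  null model is included in every step. The best single-term model is carried
  forward even if the null ranks first in a step.
* **Ties** in AICc are broken by parsimony (fewer terms), then lexicographic
  term order, for determinism.
* **CI screen**: a coefficient is informative iff its 95% CI excludes zero.
* Every fitted model is logged at INFO with its n, K and AICc.

## Slope analysis

Per-color simple regressions report slope, SE, r², the two-sided slope
p-value, and 95% prediction bands with half-width
`t·s·√(1 + 1/n + (x − x̄)²/Sxx)` (narrowest at the predictor mean; for a
*future single observation*, hence wider than a confidence band). The ANCOVA
interaction F compares the common-slope model against a separate-slopes model
parameterized with one slope per color, so the interaction model's slope
estimates coincide exactly with the stratified fits (tested as an algebraic
identity). When both models fit perfectly (noise-free, equal slopes) the F
ratio is 0/0 and is reported as F = 0, p = 1. Pairwise slope contrasts use
the studentized-range adjustment over the all-pairs family:
`q = |Δm|·√2 / SE(Δm)` referred to the studentized-range distribution with
k groups and the full model's residual df. Levene's test uses median centering
(the Brown–Forsythe robust variant), and a Kruskal–Wallis test on ΔT by color
accompanies it because the color groups typically have unequal variances.

## Biophysics calculators

`forced_convection`, `surface_heat_transfer_coefficient` and `net_radiation`
are standalone interpretive tools and are deliberately not coupled into the
regression pipeline. Net radiation requires kelvin (the fourth-power law is
meaningless in °C; a converter is provided). The h_c scaling law's exponents
and constant are user inputs — their experimental determination is
organism-specific and rarely performed, so no biological defaults are
asserted. Default emissivity is 0.93, the infrared-thermometer setting the
surface-temperature measurements assume.

## Pipeline and reproducibility

`run_pipeline` executes simulate → estimate-albedo → compare-albedo →
assemble → fit-models (both responses) → compare-slopes into a run directory,
with a manifest carrying the config hash, the master seed, per-stage seeds
derived via `numpy.random.SeedSequence(seed).generate_state` (masked below
2³¹), and a SHA-256 checksum per output file. CSV outputs are comma-separated
UTF-8 with a header row and period decimals; column names are lower-snake-case
(`temp_cow`, `temp_amb`, `delta_t`, `ktclear`, `rad_lw`, `rad_sw`, …).
Identical config + seed reproduce byte-identical outputs (tested).

## Problem sizes used by the test suite

Simulation-based checks run at the study-scale sizes: staged-selection
recovery uses 100 seeds at n = 638 and 5 °C residual noise; coefficient-CI
coverage uses 200 seeds; slope recovery and ANCOVA power use 100 seeds at 200
observations per color and 3 °C residual noise; albedo bias uses 10 noisy
scenes; oracle-equivalence checks use 100 random small instances. Replicate
seeds are derived from fixed base seeds via `SeedSequence`, so the suite is
fully deterministic.

## Known limitations

* The albedo estimator inherits every limitation of the single-reference
  ratio method: mixed illumination, shadowed references, sensor nonlinearity
  and white-balance differences all bias it, and none are modeled here.
* The copula covariate model reproduces ranges, means and pairwise
  correlation strengths only; real weather has temporal autocorrelation,
  seasonality and non-Gaussian dependence the generator does not attempt.
* Per-color albedo is assigned as a constant per color; within-color albedo
  variation is not simulated.
* The selection protocol searches only the staged candidate sets described
  above, not all subsets of all covariates.
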