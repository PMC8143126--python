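# bovitherm

Snow-referenced albedo estimation and thermal-ecology modeling for animals of
different coat colors, built for rangeland ecologists and animal scientists who
want a reproducible, scriptable version of a winter field workflow: score hide
albedo from digital photographs, relate animal surface temperatures to weather
and solar radiation by information-theoretic model selection, and compare how
different hide colors respond to ambient temperature.

## The science in brief

**Albedo from snow-referenced pixels.** In an 8-bit winter photograph that
contains fresh snow, the snow acts as an in-scene brightness reference of known
albedo (0.85). For a hide region with mean pixel brightness `Bright_cow` and a
snow region with mean brightness `Bright_snow`,

    Albedo_rel = Bright_cow / Bright_snow
    Albedo_abs = Albedo_rel × 0.85

Replicate images give per-color means and standard errors; colors are compared
with an arcsine transform, a Kruskal–Wallis test, exact one-sided rank-sum
contrasts (white > red, red > black, white > black) with Cohen's *d*, and
compact significance letters.

**ΔT and staged AICc selection.** Each observation pairs an animal surface
temperature `Temp_cow` (infrared thermometer, °C) with the ambient temperature
`Temp_amb` measured at the same moment; the signed difference
`ΔT = Temp_cow − Temp_amb` is the quantity that enters convective heat-transfer
calculations. Candidate daily covariates (dewpoint, humidity, vapor-pressure
deficit, wind, earth skin temperature, clear-sky insolation index KTClear,
long- and short-wave radiative flux) are first pruned within their data-source
group at |r| > 0.7, then selection proceeds in three steps — best single
"weather" term, best single "radiation" term, then nested combinations of the
two winners plus animal attributes (hide albedo, and `Temp_cow` when the
response is ΔT) — each step ranked by

    AICc = −2 logL + 2K + 2K(K+1)/(n − K − 1)

with Akaike weights `ω_i = exp(−ΔAICc/2) / Σ exp(−ΔAICc/2)`, a ΔAICc ≤ 2 top
set, and a final 95% CI screen (a coefficient is informative iff its interval
excludes zero). `K` counts the intercept, the slopes, and the residual
variance, so the null model has K = 2.

**Slope heterogeneity.** ΔT is regressed on `Temp_amb` separately per hide
color (with 95% prediction bands), and slope differences are tested by ANCOVA:
an F-test of the color × temperature interaction, Tukey
(studentized-range-adjusted) pairwise slope contrasts, a Brown–Forsythe Levene
test, and a Kruskal–Wallis fallback.

Because the original images and the 638-row field dataset are not public, the
package ships a first-class synthetic-data module that generates winter scenes
of known patch albedo and thermal tables with the declared covariate ranges,
correlation structure and generating coefficients, so every stage is testable
against ground truth.

## Worked example

```python
import bovitherm as bt

# a noisy synthetic winter scene with white/red/black patches
image, masks, truth = bt.generate_winter_image(bt.SceneSpec(noise_sd=5.0, seed=1))
for e in bt.estimate_image_albedos(image, masks):
    print(f"{e.label:>6}: albedo_abs={e.albedo_abs:.4f}")

# staged AICc selection on a synthetic 638-row thermal table
obs, cov, _ = bt.generate_thermal_observations(
    bt.ThermalGenParams(n=638, noise_sd=5.0, seed=1))
sel = bt.StagedAICcSelector(response="temp_cow").fit(bt.assemble_dataset(obs, cov))
print("final model:", sel.final_fit_.name)
print(sel.final_fit_.params.round(4).to_dict())
```

prints

```
  snow: albedo_abs=0.8500
 white: albedo_abs=0.6880
   red: albedo_abs=0.1610
 black: albedo_abs=0.0387
final model: temp_amb + ktclear + albedo
{'intercept': 26.7624, 'temp_amb': 0.1742, 'ktclear': 19.714, 'albedo': -26.9755}
```

The snow region scores exactly the 0.85 reference (a built-in self-check); the
patch albedos come back at their injected values up to pixel noise; selection
recovers the generating model, and the fitted coefficients sit close to the
generating values (0.1770, 19.172, −27.026). The slope analysis on slope-mode
data likewise recovers per-color slopes near the generating −0.45 / −0.92 /
−1.07 with an overwhelming interaction test (F ≈ 870, p < 1e-170 at
200 observations per color).

The same stages are available from the shell:

```sh
bovitherm run --seed 1 --out run1        # full pipeline with manifest
bovitherm simulate --out sim --seed 1
bovitherm estimate-albedo --image sim/scene.png --mask sim/scene_labels.png \
    --mapping sim/scene_labels.yaml --out estimates.csv
bovitherm biophysics net-radiation --area 1 --emissivity 0.93 \
    --t-organism 300 --t-environment 290
```

`bovitherm run` writes every stage output plus `manifest.json` (config hash,
master seed, derived per-stage seeds, file checksums); identical config and
seed reproduce byte-identical outputs.

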