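# soarlift

Fine-scale uplift modelling and flight-mode analysis for GPS-tracked
soaring birds.

Soaring birds exploit two kinds of rising air: thermals (columns of
solar-heated air, climbed in circles) and orographic lift (wind deflected
up windward slopes, soared along in straight lines). `soarlift` is for
movement ecologists who want to test, at the scale of tens of metres,
whether where and *how* a bird soars matches where the atmosphere provides
lift — for example to anticipate collision risk before siting wind
turbines. It provides the full chain:

1. **Uplift rasters** from a digital elevation model, a wind scenario and a
   land-surface-temperature raster:
   orographic uplift `w0 = v · sin(θ) · cos(α − β)` (clamped at 0 on
   leeward terrain) and the convective velocity scale
   `w* = (g·z·H/θₚ)^(1/3)` with sensible heat flux
   `H = ρ·c_p·(Tₛ − Tₐ)/r_a`.
2. **Track processing**: daylight/misreading filters, 200-s segments of
   continuous flight, and eight per-segment flight parameters (AGL,
   displacement, elevation change, ground/vertical speed, directional
   variance `1 − R̄`, tailwind component, accelerometer heave amplitude).
3. **Flight-mode classification**: K-means on (elevation change,
   directional variance), cluster count by the gap statistic with
   first-SE-max selection, centroid-based labelling into gliding /
   circular soaring / linear soaring, and boundary exclusions.
4. **Association models**: binomial GLMMs (logit link, Laplace maximum
   likelihood, crossed random intercepts for bird and day) of soaring mode
   on the two uplift velocities, Gaussian LMMs for flight-parameter
   contrasts, and Nakagawa-Schielzeth marginal/conditional R².
5. **A synthetic-data generator** that emulates the whole study — terrain,
   temperature, wind, multi-bird GPS campaigns with known generating modes
   and mode-choice coefficients — so every step is testable by parameter
   recovery without any field data.

## Worked example

Simulate a campaign (21 birds, 3 days, levanter wind from 115.7° at
10.4 m/s), build the uplift maps, classify flight modes, and fit the
linear-soaring model:

```python
import soarlift as sl

cfg = sl.SimulationConfig()
fixes, bursts, truth, dem, lst = sl.simulate_study(cfg, seed=42)
w0, w_star = sl.uplift_rasters(dem, lst, cfg)

segments = sl.segment_track(sl.filter_fixes(fixes), bursts=bursts)
table = sl.segment_table(segments, dem, cfg.wind)
labelled = sl.classify_segments(table, force_k=3, seed=42)
print(labelled["mode"].value_counts().to_string())

obs = sl.build_observations(labelled, w0, w_star)
obs, n_extreme = sl.exclude_extreme_uplift(obs, 4.5)
fit = sl.fit_binomial_glmm(obs, response_mode="linear")
print(fit.summary().round(3).to_string(index=False))
print(f"R2 marginal = {fit.r2_marginal:.2f}, conditional = {fit.r2_conditional:.2f}")
```

Output:

```
mode
circular_soaring    127
gliding             124
linear_soaring       94
excluded             78
                term  estimate    se      z     p
         (Intercept)     0.994 1.647  0.603 0.546
   thermal_uplift_ms    -1.389 1.135 -1.224 0.221
orographic_uplift_ms     0.448 0.145  3.097 0.002
R2 marginal = 0.09, conditional = 0.20
```

Reading this: of 423 segments, 78 sit at cluster boundaries and are
excluded; among the rest, a 1 m/s increase in modelled orographic uplift
raises the log-odds of linear soaring over gliding by ≈0.45 (Wald
p = 0.002) — slope soaring concentrates where wind meets windward terrain,
which is exactly the structure the generator planted (β_oro = 0.8 at bout
level; the segment-level coefficient is attenuated by within-bout movement).
The thermal term is weakly determined here because the synthetic scene's
`w*` only spans ~0.8 m/s. The same pipeline is scriptable from the shell:

```bash
soarlift simulate --seed 42 --outdir data/
soarlift uplift --dem data/dem.tif --lst data/lst.tif \
    --wind-dir 115.7 --wind-speed 10.4 --out-oro w0.tif --out-thermal wstar.tif
soarlift segment --fixes data/fixes.csv --bursts data/bursts.csv \
    --dem data/dem.tif --wind-dir 115.7 --wind-speed 10.4 --out segments.csv
soarlift classify --segments segments.csv --b 1000 --seed 42 --force-k 3 --out labelled.csv
soarlift associate --labelled labelled.csv --oro w0.tif --thermal wstar.tif --out fits.json
```

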