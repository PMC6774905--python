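# entolidar

Analysis pipeline for **dual-wavelength polarization-sensitive optical
(entomological lidar) transit signals** of flying insects, built around one
question from vector surveillance: can gravid (egg-carrying) female
mosquitoes be identified remotely from their backscatter?

Only females that have taken a blood meal become gravid, so gravidity
statistics flag the subpopulation that can carry mosquito-borne disease and
point to breeding habitat. A sensor of this kind records each insect transit
on three channels — NIR intensity I₉₂₄ and the co-/cross-polarized SWIR
intensities I₁₃₂₀,∥ and I₁₃₂₀,⊥ — sampled at 30 517 Hz as the insect crosses
a 2.54 cm FWHM Gaussian beam. The package provides, for whoever needs to
analyse (or prototype analyses of) such signals:

* **`entolidar.simulate`** — a forward model generating labelled synthetic
  transit events: Gaussian transit envelope, rectified harmonic wing-flash
  train, class-conditional draws of wingbeat frequency, depolarization
  ratios and optical cross sections, detector bandwidth and noise.
* **`entolidar.signal`** — wing/body decomposition (sliding-minimum
  envelope) and calibration to the six optical cross sections
  σ₉₂₄,w, σ₉₂₄,b, σ₁₃₂₀,∥,b, σ₁₃₂₀,∥,w, σ₁₃₂₀,⊥,b, σ₁₃₂₀,⊥,w (mm²).
* **`entolidar.features`** — the 18 predictors per event: ln of all 15
  pairwise cross-section ratios (two of which are the body and wing
  depolarization ratios δ = G·I⊥/I∥ = σ⊥/σ∥ before the log), the wingbeat
  frequency from a comb-scored Welch spectrum, and two harmonic power
  ratios.
* **`entolidar.classify`** — linear discriminant analysis written out
  explicitly (generalized eigenvectors of the between/within-class scatter
  pair, nearest projected centroid), with random under-sampling to the
  smallest class and repeated stratified k-fold cross-validation.
* **`entolidar.metrics`** — overall accuracy, per-class recall/precision/F1,
  95% confidence intervals over repeats, percent changes and the Deakin
  wingbeat–mass scaling f ∝ m^0.3.
* **`entolidar.pipeline` / `entolidar.cli`** — a deterministic end-to-end
  chain (simulate → decompose → features → evaluate) and a thin `entolidar`
  command-line wrapper (`simulate`, `decompose`, `features`, `evaluate`,
  `run`, `report`).

The gravid/non-gravid contrast built into the default class specifications:
mean body depolarization 0.62 vs 0.45 (+38%), mean wingbeat frequency 365 vs
347 Hz (+5.2%), body SWIR/NIR cross-section ratio ≈2.5 and wing ≈1.6.

## Worked example

`examples/03_gravidity_classification.py` simulates an imbalanced two-class
dataset (100 non-gravid / 210 gravid events, mirroring a ~2:1 specimen
imbalance), extracts features, and evaluates the balanced LDA with 100
repeats of under-sampling + 10-fold cross-validation:

```
                 class    precision       recall           f1
   culex_female_gravid 89.2 ± 0.33% 89.1 ± 0.49% 89.1 ± 0.35%
culex_female_nongravid 89.2 ± 0.45% 89.2 ± 0.35% 89.1 ± 0.33%

overall accuracy: 89.1 ± 0.34%  (100 repeats)
```

Accuracy far above the 50% chance level shows that body depolarization and
wingbeat frequency jointly carry the gravidity signal under the generator's
statistical assumptions; the ± values are 95% CIs over the resampling
repeats only. The other examples cover single-event simulation and
inspection (`01`), decomposition and feature extraction with truth
comparison (`02`), and the wingbeat-based egg-load mass estimate (`04`).

The same run from the shell:

```bash
python -c "import entolidar as el, entolidar.io as eio; \
           eio.dump_scenario('scenario.yaml', el.BeamModel(), el.two_class_specs())"
entolidar run --config scenario.yaml --n-per-class 100,210 --repeats 100 --seed 1 --out out/
entolidar report --in out/report.json
```

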