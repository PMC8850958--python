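# mwablate

Image-driven biophysical modelling of hepatic **microwave ablation (MWA)**
in fatty liver disease, for researchers in thermal-therapy modelling and
quantitative liver imaging.

Non-alcoholic fatty liver disease changes the dielectric and thermal
properties of liver parenchyma, and therefore the size and shape of the
necrotic zone an MWA applicator produces. `mwablate` turns voxelwise fat
percentage — as measured by chemical-shift (mDIXON-style) fat-quantification
MRI — into a full tissue property set, and simulates a 915 MHz, 60 W,
15-minute ablation with a single-slot coaxial antenna to forecast the
ablation zone across disease states.

The core models, in the field's standard notation:

* **Constitutive model** — thermal conductivity
  `k(f) = (k_liver − k_fat)·e^{τ_k f} + k_fat` (f in percent,
  τ_k = −0.0546); electrical conductivity and relative permittivity as
  volume-fraction mixtures of the liver/fat endpoint values at 915 MHz;
  blood perfusion ω_b falling linearly from 0.018 1/s (healthy) to a
  cirrhotic floor of 0.011 1/s, saturating at 35 % fat.
* **Wave equation** — `∇×(μ_r⁻¹∇×E) − k₀²(ε_r − jσ/ωε₀)E = 0`, solved in the
  axisymmetric TM₀ reduction for H_φ with a matched TEM port, perfect
  electric conductors, and a first-order scattering boundary; the field is
  normalized so the net port power equals the prescribed drive power.
* **Pennes bioheat** — `ρc_p ∂T/∂t = ∇·(k∇T) − ρ_b c_{p,b} ω_b (T − T_b) + ½σ|E|²`
  with a 37 °C exterior, saline cooling (h = 980 W/m²K, 20 °C) on the
  antenna surface, integrated implicitly.
* **Arrhenius damage** — `α(t) = ∫A·e^{−ΔE/RT(t)}dt`, damaged fraction
  `θ_d = 1 − e^{−α}`; tissue with θ_d > 0.98 is necrotic. Volume, long/short
  axis diameters, and dose–volume trajectories are extracted every 15 s.

The ROI protocol of the imaging side (1 cm circular regions avoiding
vessels, ≥40 per liver) and a synthetic-data generator for fat maps and
labelled simulation domains are included, so the whole pipeline runs
without patient data.

## Worked example

```python
from mwablate.materials import disease_property_table
from mwablate.pipeline import ExperimentConfig, run_config, percent_change

print(disease_property_table().round(4).to_string())

base = run_config(ExperimentConfig(disease_index=0))   # no infiltrative fat
high = run_config(ExperimentConfig(disease_index=4))   # high fatty liver
for name, res in [("no-fat", base), ("high-fat", high)]:
    m = res.metrics
    print(f"{name}: volume {m.necrotic_volume:.2f} cm^3, "
          f"long {m.long_axis_diameter:.2f} cm, short {m.short_axis_diameter:.2f} cm")
print("volume increase:",
      percent_change(base.metrics.necrotic_volume, high.metrics.necrotic_volume), "%")
```

prints

```
                                      0        1        2        3        4   Tumor     Fat
fat_percent                       0.000   3.9000  14.7000  21.2000  29.9000     NaN  100.00
thermal_conductivity_W_per_mK     0.521   0.4614   0.3494   0.3077   0.2708   0.624    0.21
electrical_conductivity_S_per_m   0.861   0.8317   0.7506   0.7018   0.6365   1.240    0.11
relative_permittivity            46.800  45.3960  41.5080  39.1680  36.0360  55.700   10.80
perfusion_per_s                   0.018   0.0172   0.0151   0.0138   0.0120     NaN     NaN

no-fat: volume 8.86 cm^3, long 5.20 cm, short 1.88 cm
high-fat: volume 13.67 cm^3, long 6.84 cm, short 2.17 cm
volume increase: 54.2 %
```

Each `run_config` call builds the labelled axisymmetric mesh, solves the
time-harmonic EM problem at 60 W net, integrates the bioheat equation for
900 s and thresholds the Arrhenius damage field — about five seconds per
configuration. The columns of the table are disease-state indices 0–4 plus
the tumor and pure-fat endpoints; the simulated zones show the "oven
effect": poorly conducting fatty parenchyma traps heat near the antenna and
enlarges the necrotic volume.

A command-line interface mirrors the library:

```bash
mwablate properties --out table.csv
mwablate makedata --out-dir data --state 4 --seed 1
mwablate fatquant data/fatmap_state4.nii.gz \
    --liver-mask data/fatmap_state4_liver_mask.nii.gz \
    --vessel-mask data/fatmap_state4_vessel_mask.nii.gz --n-rois 40 --seed 2
mwablate ablate --disease-index 4 --tumor --out-dir runs
mwablate run-grid --n-geometries 4 --out-dir grid
```

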