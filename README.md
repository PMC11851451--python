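# groovebind

Quantitative analysis of DNA minor-groove binders that recognize their
sites either as 1:1 monomer complexes or as cooperative 2:1 stacked
dimers — the binding mode of heterocyclic diamidines at wider minor
grooves such as -TTAA-.  The package is aimed at biophysical chemists
running SPR, native ESI-MS competition, and CD titration experiments
on ligand–DNA systems.

## What it computes

The core model is the sequential two-site (Adair) isotherm.  With
stepwise association constants K_A1, K_A2 (M⁻¹) and free ligand
concentration C (M), the binding polynomial P = 1 + K_A1·C + K_A1·K_A2·C²
gives moles of ligand bound per DNA,

    r(C) = (K_A1·C + 2·K_A1·K_A2·C²) / P,

reducing to r = K_A·C/(1 + K_A·C) for one site.  Derived metrics:

* **cooperativity index** K_coop = 4·K_A2/K_A1 — equals 1 for
  independent equivalent sites (statistical factors force
  K_A1 = 4·K_A2, i.e. K_A2/K_A1 = 0.25), > 1 for a positively
  cooperative dimer;
* **average affinity** K = √(K_A1·K_A2);
* **sequence selectivity** ratios between sites (e.g. K_TTAA/K_AATT).

Around this core:

* `kinetics` — SPR sensorgram simulation (closed-form 1:1 Langmuir,
  ODE-integrated sequential 2:1) and global multi-concentration 1:1
  kinetic fitting (`OneSiteKineticsModel.fit()` → `KineticsResults`);
* `isotherm` — plateau extraction, r = RU/RUmax normalization, and
  one-site vs two-site steady-state fitting with AIC model selection
  (`IsothermModel.fit()` → `IsothermResults`);
* `competition` — multi-DNA shared-ligand equilibrium speciation and
  native-MS neutral-mass spectrum prediction;
* `titration` — closed-cell titration curves and two-segment
  breakpoint stoichiometry (kink at ratio 1 ⇒ monomer, 2 ⇒ dimer);
* `synthetic` — seeded generators for all of the above with
  ground-truth manifests and published-constant presets;
* `cli` — a `groovebind` command with `simulate`, `fit`, `compete`,
  `titrate` and `recover` stages driven by YAML configs (explicit
  concentration units required).

## Worked example

Fit a noisy synthetic steady-state isotherm generated from the
DB1003–TTAA dimer preset (K_A1 = 2.6×10⁶, K_A2 = 7.5×10⁷ M⁻¹):

```python
from groovebind import EQUILIBRIUM_PRESETS, IsothermModel, generate_isotherm

iso, manifest = generate_isotherm(
    EQUILIBRIUM_PRESETS["DB1003-TTAA"], noise_sigma_r=0.02, seed=7
)
print(IsothermModel(iso, "two_site").fit().summary())
```

```
Steady-state isotherm fit (two_site)
==============================================
observations: 14   converged: True
param         estimate       std err
K_A1        2.3179e+06      3.36e+05
K_A2        8.3969e+07      1.25e+07
K_coop = 144.9 (positive)
K_avg  = 1.395e+07 M^-1
RSS = 0.00218777   AIC = -118.7
```

The recovered constants bracket the generating values within their
standard errors; K_coop ≫ 1 classifies the interaction as a positive
cooperative dimer, and K_avg ≈ 1.4×10⁷ M⁻¹ is the geometric-mean
affinity.  The same pattern works for kinetics:

```python
from groovebind import KINETIC_PRESETS, OneSiteKineticsModel, generate_sensorgram_set

curves, _ = generate_sensorgram_set(KINETIC_PRESETS["DB2009-AATT"], noise_sigma=2.0, seed=7)
res = OneSiteKineticsModel(curves).fit()
print(res.params)       # ka ≈ 3.34e6 M^-1 s^-1, kd ≈ 1.19e-2 s^-1, Rmax ≈ 80 RU
print(res.K_A)          # ka/kd ≈ 2.8e8 M^-1
```

Speciation of a competition mixture (two DNAs at 10 µM sharing 20 µM
ligand) and its predicted spectrum:

```python
from groovebind import generate_competition_dataset

mixture, ligand, dist, _ = generate_competition_dataset()
print(dist.free_ligand)                      # 1.894e-07 M
print(dist.per_dna["TTAA"].complex_2to1)     # 8.24e-06 M — the dominant species
print(dist.per_dna["AATT"].complex_1to1)     # 2.75e-06 M
```

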