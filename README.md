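# lnptitrate

Constant-pH titration statistics for ionizable-lipid nanoparticle (LNP)
membranes, at desk scale.

The protonation state of an ionizable aminolipid such as ALC-0315 controls
whether an LNP binds mRNA (charged, low pH) or hides its amines in a
hydrophobic core (neutral, physiological pH). In constant-pH molecular
dynamics this state is a continuous titration coordinate λ per site
(λ = 0 protonated, λ = 1 deprotonated) evolving under three analytic
potentials: a correction potential `V_MM(λ) = −ΔG_MM(λ)` fitted from
thermodynamic integration, a symmetric barrier bias `V_bias(λ)` (height
7.5 kJ/mol), and the pH driving force
`V_pH(λ) = RT ln10 (pKa_ref − pH) λ`.

`lnptitrate` implements, on top of a stochastic toy λ/depth engine that
reproduces this machinery without atomistic MD:

* **The titration statistics.** The deprotonated fraction
  `S_deprot = N_deprot / (N_prot + N_deprot)` (frames with 0.2 ≤ λ ≤ 0.8
  excluded), Henderson–Hasselbalch fits
  `S(pH) = 1 / (10^(pKa − pH) + 1)` and their generalized form with a
  cooperativity exponent `n` (`n < 1` = anti-cooperative), fitted by
  iteratively reweighted least squares (IRLS) with weights
  `h(1−h)/σ²`, parametric-bootstrap confidence intervals, block-averaged
  standard errors, and drift-ratio equilibration detection.
* **Spatial analyses.** Leaflet surfaces from median DSPC-phosphate
  positions, insertion depths, 0.25-nm depth-binned titration profiles and
  local (pKa, n) maps, core/shell composition at the 1.8-nm cutoff,
  normalized surface-charge-density titrations (pKa_LNP), density
  profiles, and membrane thickness with the slab-to-sphere LNP diameter
  estimate `d = 3t`.
* **Calibrated synthetic scenarios.** Generator presets that emit λ
  trajectories and particle traces with the statistical structure of a
  Comirnaty-like membrane patch (global apparent pKa 4.91, local pKa
  falling from ≈7.5 at the surface to ≈4 in the core, surface
  anti-cooperativity n ≈ 0.5, pH-driven fivefold membrane thickening,
  optional anionic mRNA loci).

## Worked example

```python
import numpy as np
import lnptitrate as lt
from lnptitrate.scenarios import generate_titration_table

# titration table from the HH law at the calibrated apparent pKa, with noise
points = generate_titration_table(
    pka=4.91, n=1.0, ph_grid=np.arange(3.17, 11.18, 1.0), noise_sd=0.01, seed=1
)
fit = lt.bootstrap_ci(points, model="hh", n_reps=10_000, seed=2)
print(f"pKa_app = {fit.pka:.3f}  95% CI [{fit.ci95_pka[0]:.3f}, {fit.ci95_pka[1]:.3f}]")
print(f"protonated at pH 5.5: {100 * (1 - lt.hh(5.5, fit.pka)):.0f}%")
print(f"shift vs intrinsic pKa 9.26: {lt.pka_shift_energy(9.26 - fit.pka):.1f} kJ/mol")
```

prints

```
pKa_app = 4.901  95% CI [4.868, 4.935]
protonated at pH 5.5: 20%
shift vs intrinsic pKa 9.26: 25.9 kJ/mol
```

i.e. the fit recovers the generator's apparent pKa to ±0.01, at endosomal
pH only a fifth of the aminolipids remain protonated, and the
water-to-membrane environment shift is worth ≈26 kJ/mol.

The same pipeline runs from the shell:

```bash
lnptitrate simulate --preset single_lipid_water --ph 9.26 --duration 1000 --seed 1 --out sim/
lnptitrate titrate --table table.csv --model ghh --bootstrap 10000 --out fit.json
lnptitrate report fit.json
```

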