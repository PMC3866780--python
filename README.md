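# cyclopk

Two-compartment pharmacokinetic analysis of nicardipine (NC) and its
cyclodextrin inclusion complexes — hydrophilic hydroxypropyl-β-cyclodextrin
(NC/HPβCD) and hydrophobic triacetyl-β-cyclodextrin (NC/TAβCD) — as
sustained-release oral formulations.

Nicardipine is a calcium-channel blocker with low oral bioavailability and
rapid hepatic first-pass metabolism. Complexing it with cyclodextrins
changes its dissolution profile and thereby its absorption and plasma
residence. `cyclopk` models this with linear first-order compartment
kinetics and calibrates the model against in-vivo rabbit peak data
(Cmax ± SD, Tmax), providing a tested, reproducible pipeline for anyone
comparing controlled-release formulations with small printed datasets:
pharmacokinetic modellers, formulation scientists, and students of
compartment models.

## The model

**Rate constants from half-lives.** Each compartment's first-order rate is
*k* = ln 2 / *t*₁/₂. Internally rates are min⁻¹; published tables for these
compounds quote *k*·10³, and the package keeps both conventions explicit.

**Short-range kinetics (metabolism).** The irreversible chain

    GI --k_GI--> plasma --k_Plasma--> metabolite

is *dC*/*dt* = **A** *C* with C_A(0) = 1 ng/mL, solved by matrix
exponential; the plasma compartment has the closed Bateman form

    C_B(t) = C_A(0) · k_GI/(k_Plasma − k_GI) · (e^(−k_GI t) − e^(−k_Plasma t))

with peak at T_max = ln(k_GI/k_Plasma)/(k_GI − k_Plasma), and
C_C = C_A(0) − C_A − C_B by mass conservation.

**Calibration.** Raw rates are refined by the fold
Fold = T_max·C_max^pre / (T_max^pre·C_max) (experimental Tmax/Cmax vs the
precalculated model peak), giving *k** = *k*/Fold; the refined peak is then
rescaled to the experimental time-to-peak,
C_max^val = C_max^ref · T_max^exp / T_max^ref, and compared with the
in-vivo mean ± SD.

**Long-range dosing.** Under periodic oral pulses *D*(*t*) scaled by the
dissolution ratio DR = t_complex/t_drug,

    dx/dt = D(t)·s − k_GI·x,   dy/dt = k_GI·x − k_Plasma·y

is integrated by fixed-step classical RK4 and converges to a limit cycle
with the dosing period (6 h for NC, 24 h for the complexes).

**Synthetic data.** A seeded generator draws noisy observations from the
Bateman curve (multiplicative Gaussian noise by default) and a
least-squares harness recovers (k_GI, k_Plasma), closing the loop for
self-validation without any external data.

## Worked example

The bundled configuration carries the three study compounds. Running the
validation stage:

```bash
cyclopk --verbose validate --out demo
```

prints

```
INFO cyclopk: validate NC: fold 7.14, validated Cmax 68.08 (exp 69.64 +/- 8.57)
INFO cyclopk: validate NC/HPbCD: fold 4.88, validated Cmax 39.09 (exp 39.65 +/- 1.11)
INFO cyclopk: validate NC/TAbCD: fold 5.38, validated Cmax 18.46 (exp 18.25 +/- 0.74)
```

Reading: the calibration folds are 7.14, 4.88 and 5.38; rescaling each
refined model peak to the experimental time-to-peak predicts plasma Cmax
of 68.08, 39.09 and 18.46 ng/mL, each within one standard deviation of the
in-vivo means — the complexes trade a lower, later peak for a prolonged
plasma residence. The emitted `validation.csv`/`.json` additionally carry
`discrepancy_notes` wherever a published intermediate cannot be reproduced
from its stated formula (e.g. the parent drug's refined-rate row).

The same library surface is available in Python:

```python
from cyclopk import peak
est = peak(2.88, 2.1, 1.0)   # hydrophilic complex, raw tabulated rates
print(round(est.tmax, 2), round(est.cmax, 2))   # 0.4 0.43
```

Other stages: `cyclopk rates|shortrange|longrange|synth --out DIR`
(`--config your.yaml` for custom compounds, `--strategy`, `--seed`).

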