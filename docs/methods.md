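# Methods

## Model and assumptions

All kinetics are linear and first order: absorption from the GI tract,
elimination from plasma, and hepatic conversion to the pyridine metabolite
are single rate constants, with no saturable (Michaelis–Menten) step, no
reversible transfer, no enterohepatic recirculation and no protein-binding
submodel. This is the standard two-compartment oral-dosing idealization; it
is adequate here because drug distribution is far from saturation at
therapeutic levels, and it is what makes the closed-form Bateman solution,
the matrix-exponential solution and superposition arguments exact.

Two regimes share the same rate constants but differ in forcing:

- **Short range** (metabolism after a single unit of drug in the GI): the
  closed chain GI → plasma → metabolite with C_A(0) = 1 ng/mL and no
  input. Solved as C(t) = exp(**A**t)·C(0) by eigendecomposition of the
  3×3 rate matrix (scaling-and-squaring `scipy.linalg.expm` fallback when
  the eigenbasis is ill-conditioned, i.e. near-equal rates); the contract
  is agreement with an independent fixed-step RK4 oracle, not a specific
  algorithm.
- **Long range** (repeated dosing): the open system driven by a periodic
  dose train, integrated by classical fixed-step RK4.

## Units and the ×10³ display convention

Rates are min⁻¹ internally, k = ln2/t_half. Published rate tables for
these compounds print k·10³ (a pure display convention; the printed unit
"mL/min" is dimensionally wrong for a first-order rate, and only the
ln2/t_half reading reproduces the tabulated entries from the stated
half-lives). The **short-range model uses the ×10³ magnitudes at face
value** (k_GI = 23.1 min⁻¹ for NC, etc.): only that reading produces the
reference sub-minute peaks (Tmax^pre = 0.07 min for NC). Since rescaling
all rates by a common factor only rescales time, concentrations are
unchanged and the time axis is mapped back to physiological units by the
final Tmax rescaling (below). Both conventions are explicit in code
(`RateConstants.display`, `PRINTED_TABLE1/2`).

## Calibration chain on printed values

The fold refinement and validation deliberately chain on the *published
rounded* intermediates rather than full-precision values: the reference
folds (7.14, 4.88, 5.38) follow from the rounded peak inputs
(0.58 ng/mL, 0.07 min, 69.64 ng/mL, …), and the validated concentrations
(39.09, 18.46 ng/mL) from the rounded refined peaks. Full-precision
computed values are always produced alongside; any value differing from
its published counterpart by more than one unit in the last printed digit
is recorded in `discrepancy_notes` / flagged in the rate-table report,
never silently accepted. Known irreconcilables surfaced this way:

- Raw table, NC/TAβCD GI entry: ln2/(2.2 h) gives 5.25 on the display
  scale vs the printed 5.28 (3 ulp; the printed value is consistent with
  the 4.38 absorption-rate ratio, suggesting a back-calculated half-life).
  Likewise 2.88 vs computed 2.89 and 1.56 vs 1.57 (1 ulp each, accepted).
- Refined table, NC row: 23.1/7.14 = 3.24 and 7.2/7.14 = 1.01, not the
  printed 3.18/0.99 under any rounding; the formula's value is computed
  and the row flagged.
- The NC precalculated peak evaluates to 0.590 ng/mL; the reference quotes
  0.58 for the raw run and 0.59 for the refined run. One ulp — within the
  acceptance band, noted here for completeness.

The validation step's rescaling formula, C_max^val = C_max^ref ·
T_max^exp/T_max^ref, maps the compressed short-range peak to plasma units
at the observed time-to-peak; it reproduces all three published validated
values (the NC value as 68.08 vs the quoted 68.07, attributed to upstream
intermediate rounding and carried as a note).

## Hydrophobic-complex adjustments

For NC/TAβCD the initial GI concentration is divided by the absorption
ratio k_GI(NC)/k_GI(NC/TAβCD) = 4.38. The companion "×2.5 on plasma"
adjustment is ambiguous in provenance, so it is a strategy enum:
`output_scale` (default — the reported plasma series is multiplied by 2.5,
kinetics untouched) or `slow_elimination` (k_Plasma divided by 2.5,
prolonging residence). Neither reproduces the reference TAβCD peak pair
(0.18 ng/mL, 0.44 min): output scaling gives (0.34, 1.76 refined) and slow
elimination (0.17, 2.47 refined) vs the quoted (0.18, 2.34). The chosen
strategy is recorded in every output and the deviations land in
`discrepancy_notes`; the validated TAβCD concentration (18.46 ng/mL) is
unaffected because it chains on the published refined peak.

## Long-range numerical choices

- Dose pulse shape is not specified by the source analysis; default is a
  rectangular pulse of width 0.5 h (bolus available), with the integral of
  the input over a period equal to dose × dissolution scaling for every
  shape. Consequence: absolute long-range peak heights depend on the pulse
  shape and absolute dose and are matched only qualitatively; the
  quantitative long-range claims checked are structural — limit-cycle
  period equals the dosing period, nonnegativity, superposition, RK4
  4th-order convergence, and the analytic mean plasma level on the cycle
  (dose per period / (T·k_Plasma), matched within 1 % for bolus dosing).
- Long-range elimination is first order (k_Plasma·y). The source equation
  as printed contains a time-proportional elimination term; that reading
  admits no periodic steady state and is treated as a typographical
  artifact.
- Defaults: dt = 0.01 h, horizon 15 dosing periods, burn-in 10 cycles.
  dt ≥ (1/k_max) is refused, dt ≥ (1/k_max)/10 warns. Pulse-edge
  membership uses a 1 ns tolerance on the phase so float jitter in
  t mod period cannot mis-deliver mass for pulses a few steps wide.
- Dose amounts: base dose 0.49 μg/mL (the precalculated hydrophilic-
  complex concentration) with dissolution scalings 1/12 (NC) and 1/32
  (NC/TAβCD) from the dissolution-time ratios 180/15 and 480/15; the
  absolute base dose is a free config value.

## Short-range numerical choices

Default grid 0–30 min at 0.01 min (covers the peaks at < 2.5 min and the
metabolite plateaus at 5.5/15/26 min). Bateman evaluation switches to the
degenerate limit c₀·k·t·e^(−kt) only below a relative rate gap of 1e-12;
the two-exponential form is accurate to well under 1e-6 down to gaps of
1e-6. Mass conservation is enforced at 1e-8 of the initial total, with
round-off clipped at 0. Solver equivalence (matrix exponential vs closed
form vs RK4 at dt = 1e-4 min) is verified on 0–10 min for all three
compounds — every peak and decay completes well inside that window — at
1e-6 max-absolute on the unit-C₀ scale; observed agreement is ~1e-13.

## Synthetic data and recovery

The generator samples the Bateman curve on a log-spaced schedule
(default n = 25 over 0.1–30 min; the recovery studies use n = 50) and
applies multiplicative Gaussian noise of stated CV (additive available);
negative values are clipped to zero with the clipped fraction reported,
and all randomness flows from the model's single seed. This emulates the
mean ± SD structure of the reported plasma data; it does **not** emulate
between-animal variability, serial correlation, assay detection limits or
non-Gaussian error, so passing recovery tests demonstrate identifiability
under the model's own assumptions, not robustness to real assay data.

The fitter is nonlinear least squares in log-rate space (positivity by
construction; monotone trust-region steps, parameter tolerance 1e-10).
With the amplitude free the Bateman family is exchangeable in its rates —
swapping them with amplitude rescaling c₀ → c₀·k_GI/k_Plasma leaves the
curve invariant — so estimates are normalized to k_GI > k_Plasma, the
ordering of all three study compounds. Degenerate inputs (constant series,
fewer than 4 points, near-singular Jacobian) return a non-converged result
with diagnostics instead of raising. Measured performance at CV = 0.05,
n = 50, 100 replicates: median relative error per rate ≈ 1–2 % (the test
bound is 10 %); noise-free recovery is exact to ~1e-15.

## Known limitations

- Compartment topology is fixed to the 3-species irreversible chain for
  the short range and the 2-species forced system for the long range.
- No unit framework beyond min/h; concentrations are ng/mL (long-range
  dose in μg/mL as quoted).
- The calibration chain inherits the reference analysis's rounding
  conventions by design; users fitting their own compounds get the
  full-precision path plus flags, not silent conformance.
- No population/hierarchical modelling, no statistical test of
  predicted-vs-experimental agreement (only the within-one-SD criterion;
  raw animal data are unavailable).
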