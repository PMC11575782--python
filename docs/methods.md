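# Methods

## Model and assumptions

The enzyme is a four-state continuous-time Markov system over free inactive
(`E_I`), free active (`E_A`), active substrate·ATP-bound (`E_AS`) and one
inhibitor-bound state; which bound state exists depends on the drug's
conformational selectivity (imatinib/ponatinib bind only the inactive
conformation, dasatinib only the active one). The simplification rests on:
ATP-competitive binding (inhibitor and ATP are mutually exclusive),
inhibitor binding blocking substrate association, negligible substrate
affinity of the inactive conformation, and lumped binding steps. Substrate
is clamped at `[S] = 10 µM` (perfect replenishment; substrate is not a
dynamic species) and ATP is in surplus, so catalysis `E_AS → E_A` at `kcat`
releases product and returns free active enzyme. Product is tracked as a
rate, `dP/dt = kcat·[E_AS]`; no downstream cell-population dynamics are
modelled. Total enzyme is `[E_tot] = 1 µM`, conserved exactly by the
generator's zero column sums.

The untreated quasi-equilibrium occupancies are proportional to the weights
`{1, f, f·[S]/K_M}` with `f` the Boltzmann factor of the inactive→active
free-energy difference. This is the exact `R = 0` fixed point of the rate
matrix (the derived rates satisfy `[S]/K_M = konS·[S]/(kcat+koffS)` and
detailed balance between the conformations), and it is the initial
condition of every treatment simulation. With inhibitor, the same
construction adds a bound-state weight `[R]/R_D`, giving closed-form
reference rates; at any constant `[R]` the rate is
`rate(0)·IC50/(IC50+[R])`, which the simulations reproduce to 1e-6 after
equilibration and which pins the half-rate point exactly at `[R] = IC50`.

### The conformational factor

The free-energy difference enters only through `f = e^(−βΔG)`. The default
convention (`effective_unity`) takes `f = 1` for every variant: the
wild-type difference is of order −1 kcal/mol and the mutational shifts are
fractions of kcal/mol, and the unity factor is the effective
parameterisation under which every published derived constant (the R_D and
substrate-rate tables) is reproduced cell by cell. It also makes the
conformational exchange symmetric, `ktransA = ktransI` (60 min⁻¹; 55 min⁻¹
for G250E, whose stability shift is largest). The literal convention
(`per_mole_RT`, `f = exp(−(ΔG_WT+ΔΔG)/RT)` with R in kcal/(mol·K)) is
provided for sensitivity analysis; under it `ktransI/ktransA = f` is
maintained by detailed balance. ΔΔG values are consumed as shipped
constants; the free-energy-perturbation protocol that produced them is out
of scope.

## Units

Two explicit unit domains that never mix: the inhibitor side works in nM
(IC50, R_D, plasma concentration, `konR` in nM⁻¹min⁻¹), the
enzyme/substrate side in µM (`K_M`, `[S]`, `[E_tot]`, `konS` in
µM⁻¹min⁻¹); all times in minutes (PK inputs in hours are converted on
ingestion). `konR·[R]` and `konS·[S]` both reduce to min⁻¹, so no
expression ever needs a nM↔µM conversion; field names carry their units.
This matches the units the input tables are printed in and removes the
silent 10³-error surface that a single canonical concentration unit would
create at ingestion.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `[S]` | 10 µM | clamped substrate concentration |
| `[E_tot]` | 1 µM | total enzyme |
| `ΔG_WT` | −1 kcal/mol | wild-type inactive→active difference (cancels under the unity convention) |
| `τ` | 24 h | dosing interval |
| `F` | 1 | oral bioavailability, all drugs |
| course | 10 days | daily doses; steady state is reached well before day 10 |
| IRP midpoint | 9.5 days | half an interval after the day-10 dose |

## Pharmacokinetic constants: printed vs derived

`Γ`, `α`, `ε` can be recomputed from the raw inputs (`derived` mode) or
taken verbatim from the shipped table (`printed` mode, default). The two
agree to print precision for ponatinib and dasatinib, but the shipped
imatinib `Γ = 2112.46 nM` is inconsistent with the listed `V_d = 435 L`
(the formula gives 1942.6 nM; the printed value implies ≈400 L). Printed
mode is the default so simulations run on the constants the published
indicator values correspond to; in printed mode `ka` and `ke` are
back-solved from `α` and `ε` so the curve is self-consistent (for
dasatinib this makes `ε = 64` exact, which is what the IRP value is
sensitive to). The shipped dasatinib residence-time pair is likewise
internally inconsistent (`1/249 min ≠ 0.00233 min⁻¹`); the printed `koffR`
column is used because every downstream derived constant is consistent
only with it.

## Numerics

- **Overflow-safe PK evaluation.** `α^j` reaches 10¹⁷⁰ within a course;
  the accumulation sums are always evaluated as per-dose decaying
  exponentials `e^{−k(t−jτ)}`, mathematically identical and bounded by 1.
  Closed form and brute-force dose superposition agree to 1e-9 relative.
- **Integration.** Default is LSODA (rtol 1e-8, atol 1e-12) on the linear
  non-autonomous system, with the time axis split at dose times where the
  concentration curve has slope breaks, and the analytic Jacobian
  supplied. The system is mildly stiff (rates from ~5·10⁻³ to ~800 min⁻¹).
  A forward-Euler reference at a 1 ms step (numba-compiled) is retained;
  adaptive and Euler product rates agree to ~2·10⁻⁸ relative on a 1-day
  window, far inside the 0.1 % equivalence requirement. A 10-day, 14 400
  sample run takes ~0.3 s.
- **Output grid** 1 min; IRP needs at most minute resolution and the
  9.5-day midpoint falls exactly on the grid.
- **Guards.** States more than 1e-12 µM below zero raise a stability error
  advising a smaller step (distinguishing instability from round-off);
  enzyme totals drift < 1e-11 relative over 10 days.
- **Equilibration windows** for constant-concentration cross-checks are
  sized from the slowest nonzero eigenvalue of the rate matrix (12
  decades of decay) rather than a fixed horizon.

## Synthetic variants

`synthesize_variant` draws `kcat`, `K_M` and per-drug IC50s log-uniformly
over ranges spanning the measured panel (kcat 3–200 min⁻¹, K_M 0.5–25 µM,
IC50 1–11 000 nM), plus a conformational shift and an ATP-site flag. It
emulates the *parameter space* of kinase variants, not their biology: no
correlation structure between kcat, K_M and IC50, no binding-mode-specific
IC50 patterns. Property tests over 100 seeded variants therefore establish
that the derivation and integration machinery is internally consistent
(R_D·konR = koffR, Michaelis identity, closed-form agreement, IC50
halving) across the whole plausible range — they do not validate the
biological realism of any particular parameter combination.

## Dose-time jitter

Real patients do not dose on a metronome. The schedule supports a centred
uniform perturbation (half-width in hours, seeded) of every dose time
after the first; the first dose anchors `t = 0` so the concentration
starts at zero. Jittered curves are evaluated by explicit superposition
over the actual dose times; zero width reproduces the regular closed form
to machine precision.

## When quasi-equilibrium reasoning breaks down

The effective IC50 ratio predicts the simulated IRP well at the inter-dose
midpoint for the slow-elimination drugs (within ~0.2 pp for imatinib and
ponatinib with E255K). Pointwise in time the agreement is much weaker than
a naive timescale argument suggests: binding relaxation (~13 min for
ponatinib at steady state) lags the absorption ramp after each dose
(~20 % transient rate deviation for E255K×ponatinib) and dasatinib's
64-fold daily concentration swing leaves the bound state far from
equilibrium at the trough (relative deviations of several hundred percent
for low-IC50 variants, and a 7 pp midpoint IRP gap for Y253H-E255V).
This is a genuine prediction of the dynamic model — and a caveat for any
indicator built purely from instantaneous concentrations.

## Known limitations

- One-compartment PK, no protein binding, no nonlinear clearance, no
  inter-patient variability; bioavailability fixed at 1.
- Rate constants for mutants rest on the transfer rules above, not on
  per-mutant binding kinetics measurements.
- IRP is a biochemical indicator; the map from product formation rate to
  cell growth and clinical resistance is outside the model.
- The report annotates resistance associations but deliberately does not
  hard-classify by an IRP threshold.
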