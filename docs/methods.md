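# Methods

## Reactor model and data model

The reactor is treated as an ideal plug-flow vessel of working volume
`V_tot` (default 1.0 L) demarcated into three sequential zones (inlet,
middle, effluent) of cumulative volume 0.33, 0.66 and 1.0 L. Samples are
taken at zone outlets; the feed row of an observation table carries the
inlet composition. The dilution rate `D` (h⁻¹) is the reactor-level `F/V_tot`
(reciprocal hydraulic retention time), so the cumulative segment ending at
volume `V` sees `F/V = D·V_tot/V` and residence time `τ = V/F`.

Concentrations are canonically mg/L of the dissolved anion; millimolar
values are converted at I/O boundaries with anion molar masses (sulfate
96.06, lactate 89.07, propionate 73.07, acetate 59.04, citrate 189.10,
sulfide-as-HS⁻ 33.07 g/mol). The anion basis is deliberate: the sodium-salt
feed masses and the molarities quoted for them are mutually inconsistent
under any common salt hydrate, whereas the anion basis reproduces the
1.0 g/L ↔ 10.4 mM sulfate correspondence exactly. Default feeds therefore
fix the molarities directly (13.3 mM lactate or 15.3 mM acetate, 1.16 mM
citrate, 1 000 mg/L sulfate), and the configuration accepts explicit molar
feeds for users who prefer the alternative reading.

Biofilm cell densities are normalised to the subzone volume (0.167 L) minus
the 4 % displaced by the polyurethane packing, i.e. 160.32 mL per subzone at
the defaults.

Rows flagged `excluded=true` (non-steady states after a dilution-rate step)
stay in the table and are filtered downstream; nothing about particular
dilution rates is hard-coded.

## Plug-flow kinetics

For the irreversible rate law `r_A = k·C^n`, integrating `dC/dτ = −k·C^n`
gives

- `n = 1`: `C_A(τ) = C₀·exp(−k·τ)`
- `n ≠ 1`: `C_A(τ) = [C₀^(1−n) + (n−1)·k·τ]^(1/(1−n))`

with a complete-conversion clamp at `C_A = 0` when the bracket reaches zero
(possible for `n < 1`, where substrate exhausts in finite time; the event is
recorded in the fit trace). The exponential branch is used within
`|n − 1| < 1e-9`; the power form converges continuously onto it. Both forms
are property-tested against adaptive numeric integration of the ODE
(`solve_ivp`, rtol 1e-10) to ≤1e-6 relative over `n ∈ [0.5, 5]` and
conversion extents `k·τ·C₀^(n−1)` up to 20.

The fitted observable is the segment-mean volumetric rate
`y = (F/V)·(C₀ − C_A)`, one point per cumulative volume per steady state
(up to 27 points over the nine-step ladder; the three cumulative datasets
are fitted jointly by default, with an inlet/composite/whole filter for
per-panel fits). Parameters are estimated by minimising
`SSE = Σ(y − ŷ)²` with `scipy.optimize.least_squares` in
`(log₁₀k, n)`; because k and n are strongly correlated (k spans decades as
n moves), an 80-point start grid (orders 0.5–4 in steps of 0.5 × k decades
10⁻⁹–10⁰) is screened and the best eight starts polished, with ties broken
toward the smaller order. Bounds are `n ∈ [0.2, 6]`, `log₁₀k ∈ [−15, 3]`.
Tests require the result never to lose to a 40×40 grid-search oracle on the
same bounds, and repeated fits to agree to 1e-8 relative (the procedure is
deterministic). A single-point fixed-order fit is solved exactly by
monotone bracketing (`brentq` on log k).

Goodness of fit follows the conventional definitions: `R² = 1 − SSE/SST`,
`dof = N − p` (p = 1 with the order fixed, 2 free), `SE = √(SSE/dof)`
(interpreted with the square root so that the confidence band carries rate
units), and a 95 % band of constant half-width `t₀.₀₂₅,dof·SE` around the
fitted curve. A fixed-order fit is accepted with a single point (dof 0, SE
and t undefined as NaN), since the one-parameter law interpolates it
exactly; bands require dof ≥ 1.

## Donor attribution ledger

All ledger arithmetic is molar. The reaction set (coefficients carried as
data, with their standard transformed Gibbs energies) is:

| id | reaction | ΔG°′ (kJ) |
|---|---|---|
| ACETATE_OX | acetate⁻ + SO₄²⁻ → 2 HCO₃⁻ + HS⁻ | −47.6 |
| PROPIONATE_OX | propionate⁻ + 0.75 SO₄²⁻ → acetate⁻ + HCO₃⁻ + 0.75 HS⁻ + 0.25 H⁺ | −37.7 |
| LACTATE_INCOMPLETE | lactate⁻ + 0.5 SO₄²⁻ → acetate⁻ + HCO₃⁻ + 0.5 HS⁻ | −80.2 |
| LACTATE_COMPLETE | 2 lactate⁻ + 3 SO₄²⁻ → 6 HCO₃⁻ + 3 HS⁻ + H⁺ | −225.3 |
| LACTATE_FERMENT | 3 lactate⁻ → acetate⁻ + 2 propionate⁻ + HCO₃⁻ + H⁺ | −70.0 |

Per zone, attribution proceeds in a fixed order: (1) the net propionate
change — production implies lactate fermentation (1.5 lactate and 0.5
acetate per propionate), consumption implies propionate oxidation; (2)
lactate consumed beyond the fermented share is oxidised incompletely,
capped at the remaining observed sulfate removal; (3) the residual removal
debits the acetate pool 1:1, the inlet pool including the fixed
yeast-extract credit (268 mg/L ⇒ 4.54 mM acetate, constant across dilution
rates). Removal that survives acetate exhaustion is reported as unexplained
with a deficit flag. Negative intermediates (net lactate production,
fermentation exceeding consumption, negative sulfate removal) are flagged
and floored, never raised — measurement noise must not crash the pipeline.

Residual sulfate is routed through ACETATE_OX rather than an explicit
complete-oxidation pathway: per mole of lactate, incomplete oxidation
followed by oxidation of the produced acetate is species-for-species
identical to LACTATE_COMPLETE (asserted numerically in the tests on random
amounts, for every ledger species; the printed proton coefficients of the
two routes differ by 0.5 H⁺ per lactate, an internal inconsistency of the
source table that the ledger does not track). Citrate (1.16 mM in the feed,
consumed in the inlet) is excluded from the sulfidogenic ledger by default
and only credited as an acetate source under an explicit sensitivity flag.

Zone predictions chain on **observed** upstream compositions by default —
each zone's prediction is conditioned on its measured inlet — with a
`predicted` chaining mode that propagates the predicted acetate forward;
the mode is recorded in every output.

## Synthetic data generator

The generator defines the study conditions: the nine-step dilution ladder
0.010, 0.014, 0.016, 0.018, 0.021, 0.024, 0.028, 0.032, 0.042 h⁻¹; three
cumulative volumes per steady state; five replicate samples per
measurement; Gaussian noise of 5 % CV truncated at zero (the magnitude is a
configurable stand-in — the source tables publish only that replicate SDs
exist, not their size). Noise is applied at replicate level and summarised
to mean/SD, so the emitted tables have the same provenance structure as
real ones; identical seeds give byte-identical files. Feed rows are exact.

Two named scenarios carry the reference truths: `lactate-reactor`
(first-order, k = 0.06955 h⁻¹, a fermentation schedule of 2.3 mM net
propionate per steady state elevated to 4.6/3.9 mM at the 0.014/0.016 h⁻¹
upset, which are flagged non-steady) and `acetate-reactor` (n = 2.9,
k = 1.5×10⁻⁷ mg⁻¹·⁹L¹·⁹h⁻¹, 0.014 h⁻¹ flagged). The fermentation schedule
is an explicit input, not an emergent community model. Donor allocation
runs the attribution rules forward, so `attribute_zone_sulfate` inverts the
generator exactly at zero noise — the full-circle tests (rate-law recovery
to 0.1 % in k at fixed order and ±0.05 in free order; 0 % acetate
prediction error) exercise precisely this identity.

What the generator does **not** emulate: transient dynamics between steady
states, axial dispersion or other non-ideal hydrodynamics, biomass growth
and retention feedbacks on the rate law, sulfide inhibition, pH/redox
chemistry, and analyte-specific error structure (heteroscedasticity beyond
a constant CV). Passing tests therefore demonstrate internal consistency of
the estimation and attribution machinery under the stated assumptions, not
the adequacy of those assumptions for any particular physical reactor.

## Monte-Carlo recovery conditions

Order-recovery simulations use 200 replicate ladders at 5 % CV and five
samples per measurement, truths n ∈ {1, 2, 3}. The rate constants for the
n = 2 and n = 3 truths (7×10⁻⁵ and 7×10⁻⁸) were chosen to match the
first-order scenario's initial rate `k·C₀^(n−1) ≈ 0.07 h⁻¹` at
C₀ = 1 000 mg/L, so all three regimes produce comparable conversion ranges
over the ladder. The acceptance band is the median recovered order within
±0.3 of truth — the k–n correlation makes individual noisy fits wander, but
the median is a stable statistic at these settings. Noisy replicate means
above the feed concentration are floored at the feed (a negative rate
carries no information under an irreversible rate law).

## Numerical and design choices

- Optimiser: a bounded trust-region least-squares solver replaces the
  original spreadsheet GRG solver; correctness is defined against the
  grid-search oracle, not a named algorithm.
- `R²` is left unclamped (negative for fits worse than the mean predictor);
  zero-variance observations with nonzero SSE raise rather than return an
  undefined value.
- Machine-readable outputs keep ≥10 significant digits; observation tables
  are written at 12 significant digits so that load→write→load round-trips
  are stable well below every tolerance used.
- Exit codes of the CLI: 0 success, 2 usage/input error, 3 numerical
  failure (infeasible scenario, underdetermined fit).

## Known limitations

- The ledger's fixed attribution order (propionate, lactate, acetate) is an
  identifiability convention, not a kinetic claim; co-occurring pathways
  within a zone cannot be distinguished from boundary data alone.
- The yeast-extract credit is a constant independent of dilution rate and
  applied wholly to the inlet zone.
- Free-order fits on narrow conversion ranges are weakly identified (k and
  n trade off); report both the fixed- and free-order fits when in doubt.
- No Monod/saturation kinetics, biomass-growth coupling, or residence-time
  distribution corrections; steady states only.
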