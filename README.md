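# srbkin

Plug-flow kinetics and electron-donor mass balances for sulfate-reducing
packed-bed bioreactors.

Biological sulfate reduction (BSR) treats sulfate-rich wastewater by letting
sulfate-reducing microorganisms (SRM) couple sulfate reduction to the
oxidation of an electron donor such as lactate or acetate. In an up-flow
anaerobic packed-bed reactor (UAPBR) the feed rises through a packed biofilm
carrier, so concentrations change continuously along the reactor height —
approximately as in an ideal plug-flow reactor (PFR). Sampling the reactor at
intermediate zone boundaries turns one vessel into several observation
volumes per steady state, which is enough to identify an empirical rate law
and to ask *which* electron donor paid for the sulfate removed in each zone.

`srbkin` is for bioprocess engineers and environmental biotechnologists who
have (or want to simulate) zone-wise steady-state concentration tables from
such reactors. It provides:

- **Zone-wise performance**: sulfate conversion `X = (C₀ − C_A)/C₀`,
  volumetric sulfate reduction rate `VSRR = F·(C₀ − C_A)/V`, loading rate
  `VSLR = F·C₀/V`, and foam-corrected biofilm cell densities.
- **Kinetic fitting**: the irreversible rate law `r_A = k·C^n` integrated
  analytically along the PFR coordinate (`C_A = C₀·e^(−kτ)` for `n = 1`,
  `C_A = [C₀^(1−n) + (n−1)kτ]^(1/(1−n))` otherwise, τ = V/F), fitted to
  observed segment-mean rates by multi-start nonlinear least squares, with
  SSE, R², `SE = √(SSE/dof)` and two-tailed 95 % Student-t confidence bands.
- **Donor attribution**: a stoichiometric ledger that splits lactate between
  fermentation (3 lactate → 1 acetate + 2 propionate) and incomplete
  sulfidogenic oxidation (0.5 sulfate per lactate), attributes residual
  sulfate removal to propionate (0.75 sulfate each) and acetate (1:1)
  oxidation, applies a fixed yeast-extract acetate credit in the inlet zone,
  and predicts the acetate concentration leaving every zone.
- **Synthetic data**: a generator producing steady-state observation tables
  over a dilution-rate ladder (0.010–0.042 h⁻¹) with known kinetic and
  stoichiometric ground truth and seeded replicate noise, so the full
  pipeline is testable end to end.

## Worked example

Simulate the first-order reference scenario (k = 0.06955 h⁻¹, 1 g/L sulfate,
13.3 mM lactate, 5 % CV noise), fit the rate law and run the mass balance:

```bash
srbkin simulate --scenario lactate-reactor --seed 42 --out demo/sim
srbkin fit --observations demo/sim/observations.csv \
           --config demo/sim/reactor_config.yaml --order-fixed 1 --out demo/fit
srbkin balance --observations demo/sim/observations.csv \
               --config demo/sim/reactor_config.yaml --out demo/bal
srbkin report --fit demo/fit --balance demo/bal --out demo/rep
```

which prints:

```
# Sulfate-reduction analysis report

## Kinetic fit
dataset: joint
reaction order n = 1 (fixed)
rate constant k = 0.07023 1/h
SSE = 10.39; R² = 0.9964; SE = 0.7206; dof = 20; t_crit(95%) = 2.086
points = 21; excluded sulfate rows = 8

## Donor mass balance
chaining: observed
inlet: observed vs predicted acetate differ by 1.2% on average (7 points)
middle: observed vs predicted acetate differ by 2.5% on average (7 points)
effluent: observed vs predicted acetate differ by 2.6% on average (7 points)
flagged ledgers: 1
```

The fitted rate constant (0.07023 h⁻¹) recovers the generating truth
(0.06955 h⁻¹) to about 1 % despite the measurement noise; 21 rate points
come from 7 steady states × 3 cumulative volumes (0.33, 0.66, 1.0 L), the
8 excluded sulfate rows being the two non-steady dilution rates the
scenario flags. The acetate predictions agree with the (noisy) observations
to a few percent per zone; at zero noise (`--cv 0`) the differences are
exactly zero.

The same steps run from Python via `srbkin.lactate_reactor_scenario`,
`srbkin.emit_observation_table`, `srbkin.build_rate_points`,
`srbkin.fit_kinetics` and `srbkin.attribute_reactor`.

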