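# fermbal

Balance-based analysis of **closed gas-recirculating anaerobic fermenters**
— the reactor configuration used for chain-elongation studies in which the
headspace is cycled through an external H2/CO2 reservoir, keeping the gas
phase closed and fully balanceable. The package quantifies oxygen
contamination from its nitrogen signature, computes dilution-corrected
production/consumption rates, closes whole-period electron balances, builds
test-vs-control comparison tables, and correlates microbial taxa abundances
with process rates. A synthetic reactor simulator supplies ground truth for
every estimator, so the whole chain is validated end to end.

Intended users: bioprocess engineers and environmental microbiologists
running anaerobic CSTRs (lactate/acetate chain elongation, micro-aeration
studies, H2/CO2 recirculation) who need auditable component balances rather
than instrument-specific tooling.

## The core quantities

**O2 contamination via the N2 tracer.** Air that leaks into an anoxic
reactor carries N2 and O2 at the fixed volumetric ratio 3.73. The O2 is
consumed biologically; the N2 is inert and accumulates, so between two gas
samples

```
O2 rate [mL O2 L^-1 d^-1] = (Y2·Vgas,2 − Y1·Vgas,1) / (3.73 · (t2 − t1) · V_L)
```

with `Y` the N2 volumetric fraction, `Vgas` the total system gas volume
(measured, or inferred from the He tracer as `Vgas = He added / y_He`), and
`V_L` the working liquid volume. The standard error follows the
control-reactor convention: the s.d. of an anoxic control's per-interval
rates (true rate ≈ 0), scaled by 1/√n of the test period's intervals.

**Dilution-corrected rates.** A CSTR at dilution rate `D = 1/HRT` obeys
`dC/dt = r + D(C_feed − C)`, so the volumetric rate over a period is
`r = slope + D(C̄ − C_feed)` — washout of unconsumed substrate is included
by construction.

**Degree-of-reduction electron ledger.** Every flow is weighted by
γ = 4C + H − 2O − 3N electron equivalents per mole (lactic acid 12, CH4 8,
O2 −4 as acceptor); the percent closure error `100·(out − in)/in` is the
balance check, negative when part of the monitored electron pool had
unexplained consumption.

**Stoichiometry from conservation.** Reaction templates with unknown
coefficients are balanced exactly over C/H/O/N with rational arithmetic
(e.g. 3 lactate → 2 propionate + acetate + CO2 + H2O; CO2 + 4 H2 → CH4 +
2 H2O), and the electron residual is verified to close as a consequence.

**Community stage.** Count tables are rarefied to equal depth (exact
subsampling without replacement) and screened with a significance-masked
Spearman matrix (mid-rank ρ; permutation p-values at small n, p < 0.01
mask by default).

## Worked example

Simulate a contaminated reactor (true leak 220 mL O2 L⁻¹ d⁻¹ for 32 d,
methanogenesis partially inhibited at 6.05 mmol L⁻¹ d⁻¹) next to an anoxic
control (16.5 mmol L⁻¹ d⁻¹), overlay measurement noise, and run the gas
accounting:

```python
import fermbal as fb
from fermbal import gas_accounting as ga

test = fb.simulate(fb.ReactorScenario(
    duration=32.0,
    rate_schedule=[fb.RatePhase(0, 32, {"methanogenesis": 6.05,
                                        "h2_oxidation": 12.0})],
    leak_schedule=[fb.LeakInterval(0, 32, 220.0)],
    refill=fb.RefillSpec(max_volume_ml=12_000.0)))
control = fb.simulate(fb.ReactorScenario(
    duration=32.0,
    rate_schedule=[fb.RatePhase(0, 32, {"methanogenesis": 16.5})]))

noisy = fb.apply_noise(test, fb.NoiseSpec(0.05, 0.005), seed=1)
noisy_ctrl = fb.apply_noise(control, fb.NoiseSpec(0.05, 0.005), seed=2)

period = fb.RatePeriod(0.0, 32.0, "contamination")
est = ga.o2_rate_with_uncertainty(
    ga.samples_from_frame(noisy.gas, test.event_log), period, 1.0,
    ga.samples_from_frame(noisy_ctrl.gas, control.event_log),
    event_log=test.event_log, control_event_log=control.event_log)
```

This prints (formatted):

```
O2 contamination: 220 +/- 1 mL O2 L-1 d-1 (16 intervals)
CH4 production: 6.08 mmol L-1 d-1
non-CH4 H2 consumption: 19.6 mmol L-1 d-1 (2.00x molar O2 consumption)
methane vs control: 63% less (6.08 of 16.4 mmol L-1 d-1)
```

The estimator recovers the true leak (220) from the noisy N2 series; the
H2 consumed beyond methanogenesis is exactly twice the molar O2 ingress —
the 2 H2 + O2 → 2 H2O scavenging stoichiometry — and the methane contrast
reads "63% less", the arithmetic the comparison layer reproduces from any
rate pair.

The full pipeline (simulate → rates → gas → electrons → compare →
community) runs from one declarative config:

```sh
fermbal run -c config.yaml
```

writing `rates.csv`, `gas_rates.csv`, `electron_ledger.csv`,
`contrasts.csv`, correlation matrices, and a machine-readable
`summary.json`. Identical config + seed give byte-identical outputs.

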