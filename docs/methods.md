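# Methods

## System model

The simulator and every estimator share one model of the reactor: a
well-mixed CSTR (working volume `V_L`, default 1 L) whose headspace is
continuously recirculated through an external gas reservoir, forming one
closed, well-mixed gas pool. Liquid species follow

    dC/dt = Σ_r ν_r · e_r + D (C_feed − C),        D = 1/HRT

with `ν_r` the signed stoichiometric coefficients of reaction `r` and
`e_r` its volumetric extent (mmol L⁻¹ d⁻¹). Gaseous reaction participants
(H2, CO2, CH4, O2) exchange instantly with the gas pool; dissolved-gas
holdup and CO2/bicarbonate speciation are neglected, which is the standard
simplification for balances driven by gas-phase measurements. Process
rates are piecewise-constant scenario inputs, not kinetic laws: the
package's job is estimator validation, and prescribed extents make ground
truth exact. Air leaks add O2 at the scheduled rate plus N2 at 3.73 times
that rate (the volumetric composition of air); N2, He and ethylene are
biologically inert.

Integration is explicit Euler at Δt = 0.05 d. The dynamics are far from
stiff at these rates (time constants ≥ HRT = 14 d), and a fixed step keeps
every conservation statement exactly auditable: in a noiseless run the
element (C, H, O, N, He) and electron inventories close to machine
precision, which the test suite asserts at 1e-6 relative. Within a step
the order is: leak addition, reactions (with the O2-consuming extent
capped at the O2 actually present — the physical scavenging limit; any
other gas pool driven negative is an error), feed/withdrawal, reservoir
control. Withdrawal is booked at the post-reaction, pre-dilution
concentration so feed − withdrawal matches the dilution term exactly.

### Reservoir control

The reservoir recharge is 10 L H2:CO2 (80:20) + 240 mL ethylene
(methanogenesis inhibitor) + 120 mL He (tracer). The refill trigger
watches the *limiting* recharge component: for each species the recharge
provides, the recharge-equivalent volume `v(species)/share(species)` is
tracked and a refill fires when the minimum drops below 20% of the
recharge (2,072 mL). A plain total-volume trigger fails in exactly the
situations of interest — inert charge (He, ethylene) and air-derived N2
accumulate and keep the total high while H2 runs out. Scenarios with
sustained air ingress optionally cap the loop volume (`max_volume_ml`),
venting to a set volume at the current composition; every refill and vent
is a logged event with per-species volumes, and all downstream bookkeeping
(species rates, N2 accounting, He-based volume) discounts logged events.

### Measurement noise

Liquid concentrations are multiplied by lognormal deviates with median 1
and shape = CV (default 5%, a typical HPLC repeatability); gas fractions
receive additive Gaussian noise (default s.d. 0.005 absolute, typical GC
repeatability), are clipped at zero and renormalised. The simulator's
`v_gas_ml` column carries the true volume; analyses may instead derive the
volume from the He tracer, which inherits the fraction noise.

What the generator does **not** emulate: feed pulsing (the reference
operation feeds ten times per day; at HRT 14 d this is indistinguishable
from continuous feeding at the Δt scale), pH dynamics, biomass growth and
decay, inhibition kinetics and community succession (rate phases stand in
for them), gas-liquid mass-transfer limitation, and instrument drift or
calibration bias (noise is unbiased). Passing tests therefore demonstrate
correctness of the balance arithmetic and estimator statistics under the
stated noise model — not robustness to structural model error in real
reactors.

## Estimators

**O2 contamination.** Interval form
`(Y2·Vgas2 − Y1·Vgas1 + N2 vented)/(3.73·Δt·V_L)` on the N2 fraction;
exact when N2 is biologically untouched and the gas volume is known per
sample. The validity caveats are surfaced, not enforced: a warning
attaches when O2 exceeds 0.1% by volume (detection threshold; the
reference work states only "below the detection limit"), and the bias of
ignoring leak-driven volume growth is demonstrated in a test sweep rather
than silently corrected. Negative interval rates are retained in averages
— truncation would bias the mean upward, and anoxic-control summaries of
the form "7 ± 33" only make sense with signed noise kept. The period
point estimate is the duration-weighted mean of interval rates; the
standard error is the s.d. of an anoxic control's interval rates scaled by
1/√n of the test period. This control-based s.e. is deliberately
conservative: the duration-weighted mean telescopes to the endpoint
samples, so its true sampling s.d. is ≈ 1/√n of the quoted s.e.; coverage
of truth by ±2 s.e. is correspondingly high.

**Liquid rates.** `r = slope + D(C̄ − C_feed)` in two modes: least-squares
slope with sample-mean C̄ (default; robust to noise) and endpoint
differencing with trapezoidal C̄ (exact two-point bookkeeping; on
noiseless data it closes balances to <0.1% and is the mode used for
whole-period ledgers). Period boundaries are always user-supplied labels;
no changepoint inference.

**Identifiability caveat.** With multiplicative noise, the error of a
recovered rate scales with CV·C̄, not with the rate. Compounds whose
concentration is dominated by an unconsumed feed background (acetate at
200 mM against net rates of a few mmol L⁻¹ d⁻¹) cannot be recovered to
10% relative at CV 5% over a 14-d window — by any estimator. The
replicate recovery tests therefore assert the 10% band for the compounds
where the signal is commensurate with the rate (products accumulating
from zero and the substrate with a mostly-consumed feed), which is the
honest statement of what the data can support.

**Gas species rates.** Endpoint differences of `Y·Vgas` with refill
additions subtracted and vents added back, divided by 22.414 mL/mmol
(0 °C, 101.325 kPa — one declared reference used everywhere), Δt and
`V_L`. H2 attribution assumes 4 mol H2 per mol CH4 (hydrogenotrophic
stoichiometry, itself derived by the balancer); the remainder is "non-CH4
H2 consumption", reported against the H2:O2 = 2 reference of direct H2
oxidation.

**Electron ledger.** Flows are rate·duration·γ with γ = 4C + H − 2O − 3N
on the neutral free-acid formula (carboxylates are carried as free acids
throughout, which is what makes g/L and mM interchangeable). Inflows:
substrate feed, net H2 consumed. Outflows: products and residual
substrates leaving with the withdrawn broth (feed + net production), CH4,
net H2 formed, and 4 e⁻ per mol of O2 ingress (acceptor sink). He,
ethylene and N2 never enter ledgers (inert; the blanket γ convention
would assign N2 −6, an artefact of the ammonia-N reference). Biomass
(CH1.8O0.5N0.2, γ 4.2, 24.6 g/C-mol) is excluded unless an explicit rate
is supplied — optical density was monitored in the reference operation
but there is no indication biomass entered its balances. The closure
error divides by total inflow electrons ("the monitored pool"); negative
error means unexplained consumption. A net drawdown of liquid inventory
(consumption exceeding feed) books on the inflow side so all flow
magnitudes stay non-negative.

**Reaction balancing.** Unknown coefficients are solved from exact
rational element conservation (Gauss–Jordan over `Fraction`s), anchored by
at least one fixed coefficient. The electron residual is a fixed linear
combination of the element residuals (γ is linear in element counts), so
it adds no equation — it is verified, not imposed. One solution family
needs a convention: lactate → propionate/acetate/CO2/H2O retains one
degree of freedom because the direction 7 acetate ↔ 4 propionate + 2 CO2
+ 2 H2O is itself element- and electron-balanced. The balancer then
returns the unique solution in which every template species participates
with a nonzero coefficient and the coefficients are the minimal
small-integer choice (recovering the classical 2:1:1
propionate:acetate:CO2 stoichiometry); if no such canonical point exists,
or two tie, the template is rejected as underdetermined.

**Comparisons.** Stored contrasts are never rounded; the report layer
rounds half-away-from-zero to integer percent and phrases the sign
("less"/"higher"). When a previously reported figure is supplied for
cross-checking, the report flags disagreement with the recomputed value
instead of adopting the claim.

**Community stage.** Rarefaction is an exact multivariate hypergeometric
draw to a common depth (default: the smallest sample total). Spearman ρ
is the Pearson correlation of mid-ranks; p-values use a seeded
permutation test (10,000 permutations) below n = 12 and the t
approximation otherwise; cells with p ≥ α (default 0.01) are masked but
keep their ρ. Raw-p masking is the default; Benjamini–Hochberg is behind
a flag. Relative abundances are computed after rarefaction; "most
abundant" taxa default to ≥1% mean relative abundance. Time-resolved
rates are paired with community samples by period mean (same-day pairing
available via explicit sampling times).

## Validation problem sizes

The test and acceptance suites use: a 32-d contamination scenario (true
leak 220 mL O2 L⁻¹ d⁻¹, 1 L liquid, ~10–12 L gas loop with venting,
methanogenesis 6.05 mmol L⁻¹ d⁻¹) against a 32-d anoxic control
(16.5 mmol L⁻¹ d⁻¹); a 60-d scenario with all seven shipped reactions
active for ledger closure; 100 noise replicates for coverage and
recovery statements; 50 seeds for community-link detection; and 10,000
permutations against exhaustive enumeration at n = 6. These sizes give
each stochastic assertion a comfortable margin while keeping the whole
suite in the order of seconds.

## Known limitations

- Rates are extents, not kinetics: the simulator cannot express substrate
  limitation or inhibition within a phase; phase boundaries must encode
  them.
- The Euler split introduces an O(Δt) offset (≈ r·Δt) between the
  continuous CSTR fixed point and the discrete one — irrelevant to
  bookkeeping (which is exact for the discrete system) but visible if
  scenario initial conditions are set from the continuous formula.
- Gas accounting assumes a single well-mixed gas pool; reservoir/headspace
  gradients and pressure/temperature excursions are out of scope (all
  volumes are at the fixed 0 °C / 101.325 kPa reference).
- The electron ledger is rate-based; inventory drift inside a period is
  attributed via the rate identity, so very short periods with strong
  transients should use the endpoint mode with dense sampling.
- Acid/base speciation, Henry-law partitioning and ORP are not modelled;
  O2 quantification rests entirely on the N2 signature.
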