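# Example run configuration: contaminated reactor vs anoxic control,
# with a simulated community linked to the methane rate.
#
# Reference operating point: HRT 14 d, feed 133 mM lactate + 200 mM
# acetate (12 g/L each), 10 L H2:CO2 (80:20) + 240 mL ethylene + 120 mL He
# reservoir recharge. Leak rate, periods and link below are scenario
# choices (artifact defaults).

seed: 1
outdir: fermbal_out
hrt: 14.0
liquid_volume: 1.0
feed_mM: {lactate: 133.0, acetate: 200.0}

periods:
  - {t_start: 0.0, t_end: 32.0, label: contamination}
  - {t_start: 32.0, t_end: 50.0, label: recovery}

test:
  scenario:
    duration: 50.0
    rate_schedule:
      - t_start: 0.0
        t_end: 32.0
        extents: {methanogenesis: 6.05, h2_oxidation: 12.0,
                  propionate_fermentation: 0.38, chain_elongation: 0.56}
      - t_start: 32.0
        t_end: 50.0
        extents: {methanogenesis: 19.5, chain_elongation: 1.78,
                  butyrate_from_lactate: 1.5}
    leak_schedule:
      - {t_start: 0.0, t_end: 32.0, o2_rate_ml: 220.0}
    refill: {max_volume_ml: 12000.0}
    noise: {liquid_cv: 0.05, gas_sd: 0.005}

control:
  scenario:
    duration: 50.0
    rate_schedule:
      - t_start: 0.0
        t_end: 50.0
        extents: {methanogenesis: 16.5, chain_elongation: 2.12,
                  butyrate_from_lactate: 1.5}
    noise: {liquid_cv: 0.05, gas_sd: 0.005}

community:
  times: [2.0, 8.0, 14.0, 20.0, 26.0, 32.0, 38.0, 44.0, 48.0]
  link:
    taxa: [methanogen, elongator, propionate_producer, bystander]
    coefficients:
      methanogen: {ch4: 0.3}
      elongator: {n-caproate: 1.2}
      propionate_producer: {o2_contamination: 0.01}
    dispersion: 200.0
    depth_range: [4977, 4977]
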