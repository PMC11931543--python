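# Two-condition demo: choline at pH 7 and dopamine at pH 4.85,
# each scanned over three voltages above a 0.5 V threshold.
seed: 5
output_dir: demo_out
geometry: {length_m: 1.1e-3, diameter_m: 1.01e-9}
trace:
  sampling_rate_hz: 25000    # reduced from the 250 kHz instrument rate for speed
  duration_s: 40
  baseline_pa: 1000
  noise_sd_pa: 2
analysis: {filter_points: 99, min_dwell_samples: 3, n_boot: 200}
conditions:
  - ion: choline
    ph: 7.0
    mobility_m2_per_vs: 1.4e-5
    k_ads: 69.6
    k_des: 121.0
    threshold_v: 0.5
    entry_rate_hz: 8
    pbc_pa_per_v: 30
    voltages_v: [0.6, 0.8, 1.0]
  - ion: dopamine
    ph: 4.85
    mobility_m2_per_vs: 2.76e-5
    k_ads: 27.5
    k_des: 53.6
    threshold_v: 0.5
    entry_rate_hz: 8
    pbc_pa_per_v: 30
    voltages_v: [0.6, 0.8, 1.0]
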