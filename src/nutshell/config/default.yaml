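# Default run configuration: the simulated measurement campaign and the
# analysis settings. All band positions are the lipid- and carbohydrate-
# associated NIR absorptions of nutmeg/shell material; amplitudes are set
# so that lipid bands dominate in nutmeg and carbohydrate bands in shell,
# with broad water/background bands shared by both.
#
# Units: wavenumbers in cm^-1, amplitudes/offsets/SDs in absorbance units,
# population_sd and sigma_b on the log scale (unitless), levels in percent.

seed: 0

grid:
  start: 11550.0
  stop: 3950.0
  step: 4.0

design:
  n_nutmeg: 36
  n_shell: 10
  forced_levels: [3.0, 7.0]
  # 230 mixtures at 1-10% (72 forced at 3%/7% + 158 below), 77 above 10%
  per_level_counts:
    1.0: 20
    2.0: 20
    4.0: 20
    5.0: 20
    6.0: 20
    8.0: 20
    9.0: 19
    10.0: 19
    20.0: 20
    30.0: 19
    40.0: 19
    50.0: 19
  min_per_nutmeg: 7
  min_per_shell: 30
  count_range: [15, 23]

endmembers:
  nutmeg:
    baseline_offset: 0.30
    baseline_slope: 0.06
    population_sd: 0.010         # homogeneous population
    bands:
      # lipid-associated bands (stronger in nutmeg)
      - {center: 8260.0, width: 120.0, amplitude: 0.10}   # C-H stretch 2nd overtone
      - {center: 5780.0, width: 80.0, amplitude: 0.30}    # C-H stretch 1st overtone
      - {center: 5665.0, width: 70.0, amplitude: 0.22}    # sym. C-H2 1st overtone
      - {center: 4330.0, width: 60.0, amplitude: 0.28}    # C-H bend 2nd overtone
      - {center: 4250.0, width: 60.0, amplitude: 0.24}    # C-H2 bend 2nd overtone
      # carbohydrate-associated bands (weaker in nutmeg)
      - {center: 6890.0, width: 180.0, amplitude: 0.16}   # O-H 1st / C=O 3rd overtone
      - {center: 4400.0, width: 90.0, amplitude: 0.18}    # O-H/C-O combination
      - {center: 4000.0, width: 80.0, amplitude: 0.16}    # C-H/C-C combination
      # broad background/water structure
      - {center: 10300.0, width: 500.0, amplitude: 0.05}
      - {center: 7100.0, width: 600.0, amplitude: 0.08}
      - {center: 5200.0, width: 300.0, amplitude: 0.22}
  shell:
    baseline_offset: 0.34
    baseline_slope: 0.07
    population_sd: 0.030         # 3x the nutmeg variability
    bands:
      - {center: 8260.0, width: 120.0, amplitude: 0.06}
      - {center: 5780.0, width: 80.0, amplitude: 0.14}
      - {center: 5665.0, width: 70.0, amplitude: 0.10}
      - {center: 4330.0, width: 60.0, amplitude: 0.14}
      - {center: 4250.0, width: 60.0, amplitude: 0.11}
      - {center: 6890.0, width: 180.0, amplitude: 0.30}
      - {center: 4400.0, width: 90.0, amplitude: 0.36}
      - {center: 4000.0, width: 80.0, amplitude: 0.32}
      - {center: 10300.0, width: 500.0, amplitude: 0.05}
      - {center: 7100.0, width: 600.0, amplitude: 0.09}
      - {center: 5200.0, width: 300.0, amplitude: 0.28}

scatter:
  sigma_b: 0.08      # log multiplicative gain SD per replicate scan
  sigma_a: 0.02      # additive offset SD (absorbance)
  sigma_eps: 0.0005  # per-channel noise SD (absorbance)
  replicates: 5

preprocessing: msc   # one of: msc, snv, detrend_snv, msc_d1
model: svm_linear    # one of: svm_linear, pls
pls_components: 10
n_repeats: 100
include_shell_targets: true

evaluation:
  single_range: [1.0, 10.0]    # single-prediction metrics
  ensemble_range: [0.0, 10.0]  # ensemble metrics (includes blanks)
  tail_thresholds: [1.0]       # reporting thresholds for blank exceedance, %
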