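# Default generator parameters for the synthetic hemiparetic-gait cohorts.
#
# Provenance of each value:
#   [PAPER]   printed estimate from the study the pipeline reimplements
#   [DERIVED] closed-form combination of printed estimates (see docs/methods.md)
#   [DEFAULT] not printed anywhere; package default chosen once, documented
#
# Units: speeds m/s; peak N/kg; impulse N/kg*s; symmetry/share as fractions.
# The per-leg model is parameterized as (total propulsion, paretic share):
#   share_i(v)  = s0_i + (sym_speed_beta + sym_interaction_beta * s0_i + u_i) * (v - cws_i)
#   total_i(v)  = total_intercept + w0_i + (total_speed_slope + w1_i) * v
#   paretic     = share * total ;  non-paretic = (1 - share) * total
# Controls use share_i(v) = 0.5 + b0_i + (sym_speed_beta + u_i) * v with the
# left leg as numerator.

stroke:
  n_participants: 15            # [PAPER] cohort size after exclusions
  paretic_side_left_ratio: 0.5  # [DEFAULT] not reported
  cws: {mean: 0.71, sd: 0.18, min: 0.5, max: 1.1}   # [PAPER] 0.71 +/- 0.18 m/s
  cws_grid: 0.05                # [DEFAULT] treadmill speed resolution
  max_speed_margin: 0.3         # [DEFAULT] maximum speed = CWS + margin
  body_mass: {mean: 82.0, sd: 10.0, min: 60.0, max: 110.0}  # [PAPER] 80 [75, 90] kg
  peak:
    sym_speed_beta: 0.12        # [PAPER] fraction per m/s
    sym_interaction_beta: -0.24 # [PAPER]
    sym_slope_sd: 0.093         # [PAPER] between-participant slope SD
    share_at_cws: {mean: 0.40, sd: 0.10, min: 0.10, max: 0.60}  # [DEFAULT] cohort asymmetry at CWS
    total_intercept: 0.727      # [DERIVED] from printed leg effect -0.17 and share 0.40
    total_speed_slope: 2.8      # [DERIVED] printed per-leg slopes 1.6 + 1.2
    total_intercept_sd: 0.30    # [DEFAULT]
    total_slope_sd: 0.70        # [DERIVED] reproduces printed per-leg slope SDs ~0.43
    step_noise_cv: 0.10         # [DEFAULT] within-condition step-to-step CV
  impulse:
    sym_speed_beta: 0.39        # [PAPER] fraction per m/s
    sym_interaction_beta: -0.715  # [PAPER]
    sym_slope_sd: 0.057         # [PAPER]
    share_at_cws: {mean: 0.40, sd: 0.10, min: 0.10, max: 0.60}  # [DEFAULT]
    total_intercept: 0.345      # [DERIVED] from printed leg effect -0.12 and share 0.40
    total_speed_slope: 0.266    # [DERIVED] printed per-leg slopes 0.12 + (0.12 + 0.026)
    total_intercept_sd: 0.05    # [DEFAULT]
    total_slope_sd: 0.10        # [DERIVED] reproduces printed per-leg slope SD 0.070
    step_noise_cv: 0.10         # [DEFAULT]

control:
  n_participants: 16            # [PAPER]
  speeds: [0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6]  # [PAPER] randomized grid
  cws: {mean: 1.25, sd: 0.15, min: 0.9, max: 1.6}  # [DEFAULT] young-adult comfortable speed
  cws_grid: 0.05                # [DEFAULT]
  body_mass: {mean: 74.0, sd: 12.0, min: 50.0, max: 110.0}  # [PAPER] 68 [63, 89] kg
  peak:
    sym_speed_beta: 0.0052      # [PAPER]
    sym_slope_sd: 0.033         # [PAPER]
    sym_intercept_sd: 0.04      # [DEFAULT] consistent with printed intercept SE 0.012
    total_intercept: 0.20       # [DEFAULT]
    total_speed_slope: 3.46     # [DERIVED] 2 x printed 1.73
    total_intercept_sd: 0.24    # [DEFAULT]
    total_slope_sd: 0.30        # [DERIVED] 2 x printed SD 0.15
    step_noise_cv: 0.10         # [DEFAULT]
  impulse:
    sym_speed_beta: -0.0043     # [PAPER]
    sym_slope_sd: 0.019         # [PAPER]
    sym_intercept_sd: 0.04      # [DEFAULT]
    total_intercept: 0.40       # [DEFAULT]
    total_speed_slope: 0.0166   # [DERIVED] 2 x printed 0.0083
    total_intercept_sd: 0.08    # [DEFAULT]
    total_slope_sd: 0.0052      # [DERIVED] 2 x printed SD 0.0026
    step_noise_cv: 0.10         # [DEFAULT]

gait:
  cadence_intercept: 60.0       # [DEFAULT] steps/min at speed 0
  cadence_slope: 40.0           # [DEFAULT] steps/min per m/s
  stance_fraction: 0.62         # [DEFAULT] stance share of the gait cycle
  braking_amplitude_ratio: 0.8  # [DEFAULT] braking lobe amplitude / propulsion amplitude
  braking_fraction: 0.40        # [DEFAULT] braking lobe share of stance
  crossover_rate: 0.0           # [DEFAULT] injected crossover-step probability
  share_floor: 0.02             # [DEFAULT] truncation floor for the paretic share
  total_floor: 0.02             # [DEFAULT] truncation floor for total propulsion

waveform:
  fs_force: 1000.0              # [PAPER] force sampling rate, Hz
  fs_marker: 100.0              # [PAPER] motion-capture rate, Hz
  foot_ml_offset: 0.10          # [DEFAULT] m, foot centreline distance from belt midline
  crossover_ml: 0.02            # [DEFAULT] m, excursion beyond the midline for injected crossovers
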