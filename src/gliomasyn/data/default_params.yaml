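# Default parameter configuration.
#
# Growth kinetics (per hour; K, mu in cell units): calibrated once so that
# the drug-resistant subclone dominates the sensitive one at steady state,
# all four compartments settle well within 300 h, and the cancer mass sits
# in a strongly coupled C_R <-> C_S interconversion loop fed by a small C
# pool, which makes the TMZ + acridone Bliss surface on C_R net-synergistic
# (see docs/methods.md).
growth:
  alpha_N: 0.075
  delta_N: 0.015
  rho: 0.01
  K: 10000.0
  mu: 1.0
  alpha_C: 0.045
  delta_C: 0.4
  gamma_R: 0.6
  omega_S: 0.4
  alpha_CR: 0.06
  delta_R: 0.015
  omega_S_tilde: 0.25
  alpha_CS: 0.0525
  delta_S: 0.03
  gamma_R_tilde: 0.5

initial_state:
  N: 1000.0
  C: 50.0
  C_R: 5.0
  C_S: 5.0

# Pharmacodynamics. IC50s (uM): TMZ 190 (resistant) / 23.33 (sensitive);
# AC26 0.76 / 0.9; AC2 1.53 / 1.53; AC7 1.05 / 5.67. Hill exponent 2
# throughout. emax (per hour) calibrated once so the simulated 72-h
# monotherapy response of the targeted compartment crosses 50% near the
# configured IC50 (see docs/methods.md).
drugs:
  TMZ:
    r: {emax: 0.06699, eta: 2.0, ic50: 190.0}
    s: {emax: 0.10984, eta: 2.0, ic50: 23.33}
  AC26:
    r: {emax: 0.08842, eta: 2.0, ic50: 0.76}
    s: {emax: 0.06926, eta: 2.0, ic50: 0.9}
  AC2:
    r: {emax: 0.08467, eta: 2.0, ic50: 1.53}
    s: {emax: 0.07452, eta: 2.0, ic50: 1.53}
  AC7:
    r: {emax: 0.10492, eta: 2.0, ic50: 1.05}
    s: {emax: 0.05069, eta: 2.0, ic50: 5.67}

# Dose-grid ranges (uM); 100 linearly spaced levels including 0.
grid_ranges:
  TMZ: [0.0, 200.0]
  AC2: [0.0, 2.0]
  AC7: [0.0, 6.0]
  AC26: [0.0, 6.0]

horizons:
  dose_response_h: 72.0     # fixed-time readout matching a 72-h exposure
  steady_state_max_h: 300.0 # cap for steady-state readouts
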