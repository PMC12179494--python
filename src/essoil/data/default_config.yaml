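# Default configuration.
#
# Units: mg C per cm^3 of soil and hours (AWB convention); energies in
# kJ mol^-1 with Rgas = 0.008314 kJ mol^-1 K^-1.  Kinetic pre-exponentials
# and activation energies follow the Allison-Wallenstein-Bradford family of
# microbe-enzyme models (Allison et al. 2010, Nat. Geosci.), with litter
# input and uptake kinetics (I, v0U, EvU) set to the values used for the
# trait-optimization scenario sweeps.  Leaching rates and the microbial
# turnover rate are local calibration choices: dM is set so that the
# evolutionarily stable allocation at c0 = 1.17 vanishes just below 0 C,
# which places the cold-edge activity limit of the model near the freezing
# point (see README).
parameters:
  I: 5.0e-3      # litter input to SOC, mg C cm^-3 h^-1
  eC: 1.0e-5     # SOC leaching rate, h^-1 (small; keeps SOC bounded)
  eD: 1.0e-4     # DOC leaching rate, h^-1
  v0D: 1.0e+8    # decomposition vmax pre-exponential, h^-1 (AWB)
  EvD: 47.0      # decomposition vmax activation energy, kJ mol^-1 (AWB)
  K0D: 1.0e+8    # decomposition Km pre-exponential, mg C cm^-3
  EKD: 30.0      # decomposition Km activation energy, kJ mol^-1
  v0U: 1.0e+5    # uptake vmax pre-exponential, h^-1
  EvU: 38.0      # uptake vmax activation energy, kJ mol^-1
  K0U: 20.0      # uptake Km pre-exponential, mg C cm^-3
  EKU: 10.0      # uptake Km activation energy, kJ mol^-1
  dM: 3.8e-4     # microbial turnover rate, h^-1 (calibrated, see header)
  dZ: 1.0e-3     # enzyme deactivation rate, h^-1 (AWB)
  gM: 0.5        # growth efficiency gamma_M
  gZ: 0.5        # enzyme production efficiency gamma_Z
  Rgas: 0.008314 # gas constant, kJ mol^-1 K^-1

scenario:
  kind: kinetics_only  # kinetics_only | mortality_arrhenius | cue_linear
  Tref: 20.0           # reference temperature for anchored scenarios, C
  gM_floor: 0.01       # lower clip for gamma_M under cue_linear
  # mortality_arrhenius uses EdM (e.g. 25 or 55 kJ mol^-1); cue_linear uses
  # m (e.g. -0.014 per C).

kernel:
  shape: arctan
  c0: 1.17                    # competitive advantage of stronger producers
  c0_alternatives: [1.10, 1.25]  # low/high sensitivity sweep values

projection:
  mode: both
  depth: 1.0  # reference soil depth factor for global aggregation

seed: 0
log_level: INFO
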