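# Default parameters for the vein-graft adaptation model.
#
# The biological rate coefficients alpha1..alpha8 are calibration constants
# of the stochastic tissue-plasticity rules; they are configuration, not
# code.  alpha1/alpha2 are chosen so the basic solution (healthy vein at
# implantation) is stationary: division and apoptosis share alpha1, ECM
# production and degradation share alpha2.  alpha5 is the intimal growth
# gain gamma of the reduced dynamical system.
plasticity:
  alpha1: 0.05        # SMC division/apoptosis base probability per completed 12 h cycle
  alpha2: 0.05        # ECM production/degradation base probability per completed 2 h cycle
  alpha3: 168.0       # T, time of maximum macrophage activity (h) ~ one week post-op
  alpha4: 336.0       # deltaT, macrophage relaxation time (h) ~ two weeks
  alpha5: 4.6         # gain of G on intimal SMC division (gamma)
  alpha6: 0.5         # gain of strain-energy excess on ECM production
  alpha7: 0.0005      # SMC migration base probability per hour (media -> intima)
  alpha8: 4.6         # gain of G on migration
  mitotic_cycle: 12.0 # h
  ecm_cycle: 2.0      # h
  step: 1.0           # h
  allow_pre_peak_growth: false
  division_layers: [intima]          # medial proliferation off by default
  apoptosis_layers: [intima]         # paired with division so the media is stable
  ecm_layers: [media]                # per the probability table: ECM turnover in media

geometry:
  r_lumen: 0.24       # mm
  r_iel: 0.28         # mm
  r_outer: 0.30       # mm
  h: 0.005            # mm grid step
  r_smc: 0.006        # mm SMC disc radius (12 um diameter)
  r_ecm: 0.003        # mm ECM element radius
  smc_fraction: 0.25  # wall area fraction occupied by SMC discs

mechanics:
  mu: 0.0035          # Pa s, blood dynamic viscosity
  Q_target: 5.0       # mm^3/s nominal flow per unit length convention
  c: 0.1              # mm^2/h GF diffusion coefficient (steady profile insensitive)
  p_internal: 13300.0 # Pa (~100 mmHg, arterialized vein graft)
  p_external: 400.0   # Pa surrounding tissue
  E: 600000.0         # Pa venous wall Young modulus
  nu: 0.45            # nearly incompressible tissue
  penalty: 1.0e-8     # Angot penalty parameter eta

remodeling:
  delta_t: 1.0        # tissue relaxation duration per hourly cycle (relaxation units)
  substeps: 10        # IBM substeps per relaxation (dt_ibm = delta_t / substeps)
  rho: 1.0            # medium density (relaxation units)
  mu_tissue: 5.0      # medium viscosity, high-viscosity regime
  n_s: 2              # repulsion range in cell diameters
  n_e: 3              # matrix-invasion range in cell diameters
  k_S: 0.006          # mm per relaxation unit, repulsion gain (~R_SMC)
  k_E: 0.0002         # matrix-invasion gain per contributing ECM cell
  k_G: 0.0005         # chemotaxis gain (mm^2 per relaxation unit)
  random_motility: 1.0   # scale of |V_R| upper bound in units of R_SMC/delta_t
  membrane_stiffness: 0.02  # spring constant per unit rest length (force/length)
  adjust_magnitude: 1.0  # fraction of net source area routed to the lumen side
  plastic_rate: 1.0   # hourly rest-length relaxation toward current lengths
  lennard_jones_repulsion: false

dynamical_system:
  gamma: 4.6
  shear_drop: 0.5
  # baseline turnover of the cellular intimal compartment at unit gain,
  # 1/day.  Mean-field value of the agent rules: alpha1 / (mitotic cycle)
  # * 24 h = 0.05 / 12 * 24 = 0.1.
  turnover: 0.1
  smc_fraction: 0.25  # cellular share of the intimal area at baseline
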