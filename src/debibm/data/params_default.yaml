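# Default parameter set for the East China Sea hairtail (Trichiurus lepturus).
# Units follow the field conventions: energies in J, lengths in cm (structural
# unless stated), rates per day, temperatures in K (DEB block) or deg C (IBM
# block), densities in kg per km^2.

deb:
  z: 5.78            # zoom factor relative to reference L_m = 1 cm [-]
  v_dot: 0.0334      # energy conductance [cm/d]
  kappa: 0.968       # allocation fraction to soma [-]
  kappa_R: 0.95      # fraction of reproductive energy fixed in eggs [-]
  p_M_vol: 67.46     # volume-specific somatic maintenance [J/cm^3/d]
  E_G: 5240.0        # volume-specific cost of structure [J/cm^3]
  k_J_dot: 0.002     # maturity maintenance rate coefficient [1/d]
  delta_M: 0.165     # shape coefficient (preanal length) [-]
  T_A: 8500.0        # Arrhenius temperature [K]
  T_H: 297.0         # upper boundary of the tolerance range [K]
  T_L: 278.0         # lower boundary of the tolerance range [K]
  T_AH: 29000.0      # Arrhenius temperature above the upper boundary [K]
  T_AL: 11000.0      # Arrhenius temperature below the lower boundary [K]
  T_ref: 293.15      # reference temperature for rate parameters [K]
  E_Hb: 1.38e-2      # maturity threshold at birth [J]
  E_Hj: 0.105        # maturity threshold at metamorphosis [J]
  E_Hp: 5435.0       # maturity threshold at puberty [J]
  h_a_ddot: 1.12e-8  # Weibull ageing acceleration [1/d^2]
  s_G: 1.84e-4       # Gompertz stress coefficient [-]
  e_j_content: 8500.0  # energy content of reserve [J/g]
  d_V: 1.0           # specific density of structure [g/cm^3]

ibm:
  T_min: 10.0        # minimum temperature for egg development [deg C]
  R_h: 0.90          # hatching success probability [-]
  DD_min: 51.5       # degree-day threshold for hatching [deg C d]
  M_egg: 0.083       # maximum daily predation rate on eggs [1/d]
  B_eggh: 2.0e+3     # half-saturation fish density for egg predation [kg/km^2]
  M_d: 0.007         # maximum density-dependent mortality [1/d]
  B_fh: 2.2e+3       # half-saturation fish density for density mortality [kg/km^2]
  M_cm: 9.73e-4      # climate-related background mortality coefficient [1/d]
  M_flow: 4.03e-4    # river-flow mortality coefficient [1/d]
  M_rain: 6.03e-5    # rainfall mortality coefficient [1/d]
  e_age: 2.0e-6      # effect of age on mortality [1/d^2]
  Age_min: 730.0     # age threshold for ageing mortality [d]
  area: 1000.0       # reference area [km^2]
  spawn_window: [105, 288]   # spawning season [day of year]
  spawn_T_min: 14.0  # minimum temperature for spawning [deg C]
  fishing_min_length_cm: 10.0  # preanal length at first capture [cm]
  mean_individual_weight_g: 140.0  # survey abundance-to-biomass conversion [g]
  cohort_floor: 1.0e-3  # cohorts below this abundance are pruned [individuals]
  dry_to_wet: 1.0    # model-weight to survey-weight conversion factor [-]
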