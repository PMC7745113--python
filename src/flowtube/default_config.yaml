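# Default flowtube pipeline configuration.
#
# Units are stated per key; everything is converted to SI on load.
# Species property values marked "placeholder" are plausible organic-liquid
# stand-ins for unavailable measured data: no screening conclusion in this
# package depends on their exact values (feed densities and molar masses,
# which set inlet concentrations, are literature values for the neat
# reagents).

species:
  M4MAA:                      # methyl 4-methoxyacetoacetate (reactant 1)
    density_kg_m3: 1118.0     # neat liquid density
    viscosity_Pa_s: 5.0e-3    # placeholder (viscous beta-ketoester)
    molar_heat_capacity_J_mol_K: 270.0   # placeholder
    molar_mass_kg_mol: 0.14614
  DMFDMA:                     # N,N-dimethylformamide dimethyl acetal (reactant 2)
    density_kg_m3: 897.0
    viscosity_Pa_s: 1.5e-3    # placeholder
    molar_heat_capacity_J_mol_K: 250.0   # placeholder
    molar_mass_kg_mol: 0.11916
  Enamine:                    # condensation product (DTG intermediate)
    density_kg_m3: 1100.0     # placeholder
    viscosity_Pa_s: 8.0e-3    # placeholder
    molar_heat_capacity_J_mol_K: 350.0   # placeholder
    molar_mass_kg_mol: 0.20122
  MeOH:                       # methanol by-product (2 per turnover)
    density_kg_m3: 792.0
    viscosity_Pa_s: 5.4e-4
    molar_heat_capacity_J_mol_K: 81.0
    molar_mass_kg_mol: 0.03204

kinetics:
  pre_exponential_L_mol_min: 2.00e8   # measured Arrhenius pre-factor
  activation_energy_J_mol: 57930.0    # measured activation energy
  heat_of_reaction_J_mol: -50000.0    # PLACEHOLDER magnitude (exothermic);
                                      # used only by the energy balance

# Two-level factor ranges of the screening design (low, high).
factors:
  L: [1.0, 5.0]        # tubing length, m
  ID: [0.25, 1.0]      # inner diameter, mm
  Q: [0.1, 1.0]        # total flow rate, mL/min
  T: [10.0, 40.0]      # bath temperature, degC
  chi: [0.95, 1.5]     # molar feed ratio DMF-DMA : M4MAA

grid:                  # default single-run grid
  n_radial: 32
  n_axial: 400
  diffusivity_m2_s: 1.0e-9
  end_time_multiple: 5.0
  steady_tolerance: 0.01

campaign_grid:         # reduced grid for 32-run factorial campaigns
  n_radial: 24
  n_axial: 200
  diffusivity_m2_s: 1.0e-9
  end_time_multiple: 3.0
  steady_tolerance: 0.01

thermal:
  conductivity_W_m_K: 0.15     # organic-liquid scale thermal conductivity
  inlet_temperature_K: 295.15  # room-temperature feed
  energy_equation: true

synthetic:             # pseudo-experimental campaign (stand-in parameters)
  replicates: 3
  replicate_noise_cv: 0.03     # lognormal multiplicative replicate noise
  bath_bias_K: 0.0             # constant wall-temperature offset
  ambient_pull_fraction: 0.05  # wall relaxes 5% of the way to ambient
  gradient_fraction: 0.01      # extra pull growing linearly along the coil
  ambient_K: 293.15
  impurity:                    # consecutive product-consuming side channel,
    pre_exponential_per_min: 5.5e10   # TUNED stand-in (mechanism unknown)
    activation_energy_J_mol: 80000.0
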