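# Example scenario: an oligotrophic open-ocean sediment pond oxygenated from
# both the overlying bottom water and an oxic basaltic aquifer below, with
# nitrate accumulating above both boundary values.  Every package default is
# written out explicitly here.
column:
  depth_max: 70.0          # m below seafloor
  n_nodes: 200
  porosity: 0.75
  temperature: 1.5         # deg C, bottom-water value
  burial_velocity: null    # m/yr; null -> depth_max / 8.0e6 yr
  D0:                      # free-solution diffusivities, m2/yr at ~1.5 degC
    O2: 0.0372
    NO3: 0.0306
    NH4: 0.0318
    Mn2: 0.0104
  bc_top:                  # bottom-seawater Dirichlet values, uM
    O2: 250.0
    NO3: 21.0
    NH4: 0.0
    Mn2: 0.0
  bc_bot:                  # crustal-fluid Dirichlet values, uM
    O2: 200.0
    NO3: 21.1
    NH4: 0.0
    Mn2: 0.0
  om_flux_top: 6.5e-4      # mol C m-2 yr-1 buried at the seafloor
  mno2_flux_top: 2.0e-6    # mol Mn m-2 yr-1
  solute_advection: false  # burial advection of solutes neglected by default
kinetics:
  k_OM: 2.0e-7             # 1/yr, single-pool organic-matter decay
  K_O2: 3.0                # uM
  K_NO3: 500.0             # uM, apparent community-scale NO3 affinity
                           # (effectively first-order in porewater NO3)
  h1: 10.0                 # uM, O2 inhibition of denitrification
  K_MnO2: 5.0              # mol m-3
  h2: 5.0                  # uM, O2 inhibition of Mn reduction
  h3: 5.0                  # uM, NO3 inhibition of Mn reduction
  k_nit: 1.0e-2            # 1/(uM yr), bimolecular nitrification
  k_mnox: 1.0e-2           # 1/(uM yr), bimolecular Mn2+ oxidation
  rN: 0.1509433962264151   # mol N per mol C (Redfield 16/106)
noise_relative:            # multiplicative lognormal sd per solute
  O2: 0.02
  NO3: 0.02
  NH4: 0.05
  Mn2: 0.05
observation_spacing_m: 1.0
abundance:
  surface_copies: 1.0e+8   # 16S copies per g wet sediment at the seafloor
  decade_length_m: 23.0    # meters per tenfold abundance decline
  peak_fold_change: 100.0  # transition-zone abundance peak
  peak_width_m: 1.5
  noise_sd_log10: 0.15
  markers: [16S_bac, 16S_arc, amoA_AOA, amoA_AOB, nxrB, narG, nirK, nirS]
  marker_offset_log10:
    16S_bac: -0.3
    16S_arc: -0.4
    amoA_AOA: -0.5
    amoA_AOB: -2.5
    nxrB: -2.3
    narG: -2.0
    nirK: -1.8
    nirS: -2.2
community:
  n_otus: 300
  logseries_shape: 0.995
  depth_decay_m: 1.2
  decay_sigma: 1.0
  persistent_fraction: 0.08
  resurrection_probability: 0.75
  reads_per_sample: 20000
  sample_spacing_m: 2.0
  aoa_fraction: 0.25
seed: 0
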