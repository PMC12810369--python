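name: mamatkulov
water_model_tag: TIP3P
ecc_factor: 1.0
combining_rule: lorentz-berthelot
provenance_notes: >
  Mamatkulov & Schwierz 12-6 Lennard-Jones parameters for alkaline-earth
  cations, parametrized against hydration free energies, activity-coefficient
  derivatives (a_cc) and water residence times (tau). Values transcribed
  best-effort from the published tables (sigma converted to R_min/2 via
  R_min = 2^(1/6) sigma); verify against the original tables before
  production use. Monovalent Na+/Cl- are the CHARMM36 ion parameters.
params:
- {species: Mg2+, Q: 2.0, epsilon_kJmol: 3.6610, rmin_half_nm: 0.110001}
- {species: Ca2+, Q: 2.0, epsilon_kJmol: 1.8820, rmin_half_nm: 0.135257}
- {species: Sr2+, Q: 2.0, epsilon_kJmol: 1.6580, rmin_half_nm: 0.148165}
- {species: Ba2+, Q: 2.0, epsilon_kJmol: 1.2790, rmin_half_nm: 0.166686}
- {species: Na+, Q: 1.0, epsilon_kJmol: 0.1962296, rmin_half_nm: 0.136375}
- {species: Cl-, Q: -1.0, epsilon_kJmol: 0.6276000, rmin_half_nm: 0.2270}
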