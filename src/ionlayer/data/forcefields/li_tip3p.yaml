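name: li_tip3p
water_model_tag: TIP3P
ecc_factor: 1.0
combining_rule: lorentz-berthelot
provenance_notes: >
  12-6 Lennard-Jones "compromise" (CM) parameter set of Li, Roberts, Chakravorty
  & Merz for divalent cations with TIP3P water, parametrized against hydration
  free energies (dG_solv) and ion-water coordination numbers (CN); values
  transcribed from the Amber distribution of that set (kcal/mol and Angstrom
  converted to kJ/mol and nm). Monovalent Na+/Cl- are the CHARMM36 ion
  parameters. Transcription is best-effort; verify against the original tables
  before production use.
params:
- {species: Mg2+, Q: 2.0, epsilon_kJmol: 0.0426867, rmin_half_nm: 0.1360}
- {species: Ca2+, Q: 2.0, epsilon_kJmol: 0.5148035, rmin_half_nm: 0.1649}
- {species: Sr2+, Q: 2.0, epsilon_kJmol: 1.0100266, rmin_half_nm: 0.1776}
- {species: Ba2+, Q: 2.0, epsilon_kJmol: 1.8677051, rmin_half_nm: 0.1982}
- {species: Na+, Q: 1.0, epsilon_kJmol: 0.1962296, rmin_half_nm: 0.136375}
- {species: Cl-, Q: -1.0, epsilon_kJmol: 0.6276000, rmin_half_nm: 0.2270}
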