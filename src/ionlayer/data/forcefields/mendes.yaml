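name: mendes
water_model_tag: SPC/E
ecc_factor: 0.80
combining_rule: lorentz-berthelot
provenance_notes: >
  Mendes de Oliveira et al. electronic-continuum-corrected (ECC) parameters for
  Mg2+ and Ca2+, parametrized against neutron-scattering difference structure
  factors dS(Q) and validated for ion-acetate binding with charge scaling
  f = 0.80 (applied here via ecc_factor, charges stored unscaled). Values
  transcribed best-effort from the published tables; verify against the
  original tables before production use. Monovalent Na+/Cl- are the CHARMM36
  ion parameters. Sr2+/Ba2+ are not part of this set.
params:
- {species: Mg2+, Q: 2.0, epsilon_kJmol: 2.0000, rmin_half_nm: 0.080820}
- {species: Ca2+, Q: 2.0, epsilon_kJmol: 0.6000, rmin_half_nm: 0.135257}
- {species: Na+, Q: 1.0, epsilon_kJmol: 0.1962296, rmin_half_nm: 0.136375}
- {species: Cl-, Q: -1.0, epsilon_kJmol: 0.6276000, rmin_half_nm: 0.2270}
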