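# Monomer binding DOPS SUVs at high ionic strength (200 mM NaP, pH 7.4):
# electrostatic screening weakens the interaction (~2-fold higher K_D).
name: monomer_suv_200mM
species: monomer
truth:
  kd: 1.5 uM
  lipids_per_site: 30
  b: 1
protein_total: 2 uM
lipid_concentrations:
  min: 1 uM
  max: 2 mM
  n: 12
  spacing: log
r_free_nm: 3.3
r_bound_nm: 14.9
noise:
  sd: 0.03
  mode: fraction
replicates: 3
condition:
  pH: 7.4
  phosphate_mM: 200
  vesicle: SUV
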