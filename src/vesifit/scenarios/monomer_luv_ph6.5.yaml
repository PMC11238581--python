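# Monomeric alpha-synuclein binding DOPS LUVs, pH 6.5, 20 mM NaP.
# Large free->bound radius contrast: the calibrated radius conversion is required.
name: monomer_luv_ph6.5
species: monomer
truth:
  kd: 2 uM
  lipids_per_site: 30
  b: 1
protein_total: 2 uM
lipid_concentrations:
  min: 1 uM
  max: 2 mM
  n: 12
  spacing: log
r_free_nm: 3.3
r_bound_nm: 64.5
noise:
  sd: 0.03
  mode: fraction
replicates: 3
condition:
  pH: 6.5
  phosphate_mM: 20
  vesicle: LUV
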