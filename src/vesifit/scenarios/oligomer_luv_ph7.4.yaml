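# Oligomeric alpha-synuclein binding DOPS LUVs, pH 7.4, 20 mM NaP.
name: oligomer_luv_ph7.4
species: oligomer
truth:
  kd: 50 nM
  lipids_per_site: 1.0e4
  b: 35
protein_total: 2 uM
lipid_concentrations:
  min: 1 uM
  max: 2 mM
  n: 12
  spacing: log
r_free_nm: 12.3
r_bound_nm: 48.1
noise:
  sd: 0.03
  mode: fraction
replicates: 3
condition:
  pH: 7.4
  phosphate_mM: 20
  vesicle: LUV
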