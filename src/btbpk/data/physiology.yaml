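# Species-level healthy CNS physiology.
#
# The five tumor-comparable parameters (brain volume fractions of MV and
# ECF, extracellular/intracellular pH, CBF) are the healthy-brain reference
# row.  The remaining entries are companion-model fixtures: absolute
# volumes, flows, surface areas, barrier geometry and the MV/lysosomal pH,
# chosen from standard rat and human CNS physiology and versioned here.
# Property-based behaviour must hold for any positive parameterization;
# only these pinned defaults are used for printed-number checks.
#
# Units: volumes mL; flows mL/min; areas cm^2; widths/radii cm except
# pore_radius_base (nm); CBF mL/min/g; q_ecf_bulk_per_ml mL/min per mL
# tissue.
version: 1
rat:
  species: rat
  brain_volume: 1.8
  f_mv: 3.00
  f_ecf: 20.0
  v_icf: 1.3572
  v_mem: 0.018
  v_lyso: 0.0108
  v_lv: 0.05
  v_tfv: 0.05
  v_cm: 0.017
  v_sas: 0.18
  cbf: 1.53
  q_ecf_bulk_per_ml: 1.1e-4
  q_csf: 0.0022
  sa_bbb: 263.0
  sa_bcsfb: 25.0
  bbb_width: 5.0e-5
  pore_fraction_base: 1.0e-4
  pore_radius_base: 0.7
  ph_mv: 7.4
  ph_ecf: 7.30
  ph_icf: 7.00
  ph_lyso: 5.0
  ph_csf: 7.30
  cell_radius: 5.0e-4
  lysosome_radius: 3.0e-5
human:
  species: human
  brain_volume: 1400.0
  f_mv: 3.67
  f_ecf: 20.0
  v_icf: 1046.22
  v_mem: 14.0
  v_lyso: 8.4
  v_lv: 22.5
  v_tfv: 2.8
  v_cm: 7.5
  v_sas: 90.0
  cbf: 0.527
  q_ecf_bulk_per_ml: 1.1e-4
  q_csf: 0.35
  sa_bbb: 150000.0
  sa_bcsfb: 5000.0
  bbb_width: 5.0e-5
  pore_fraction_base: 1.0e-4
  pore_radius_base: 0.7
  ph_mv: 7.4
  ph_ecf: 7.30
  ph_icf: 7.00
  ph_lyso: 5.0
  ph_csf: 7.30
  cell_radius: 5.0e-4
  lysosome_radius: 3.0e-5
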