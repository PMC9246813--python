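# Reference results of the two-stage estimation on the source microdialysis
# studies, bundled for structural checks and demos (the underlying digitized
# concentration data are not packaged, so these numbers are inputs, not
# outputs, of this package).
#
# kpuu: measured steady-state unbound ECF/plasma ratios per study arm.
# ppa_corrections: fitted paracellular-permeability correction factors
#   (fold-decrease) for the control-brain barrier; "applied" false means the
#   estimate had negligible impact and factor 1 was used downstream.
# fold_changes: blood-tumor-barrier fold changes over the control-brain BBB
#   (paracellular pore size; active efflux clearance).  One case per
#   drug-model pair; the human methotrexate case covers patients A and B.
version: 1
kpuu:
  rat:
    methotrexate_sham: {control: 0.114, tumor: 0.105, tumor_model: RG-2}
    methotrexate_healthy: {control: 0.118, tumor: 0.250, tumor_model: R-6}
    methotrexate_contralateral: {control: 0.00527, tumor: 0.123, tumor_model: CNS1}
    temozolomide: {control: 0.262, tumor: 0.227, tumor_model: SF188}
    ganciclovir: {control: 0.269, tumor: 0.785, tumor_model: BT4C}
    gemcitabine: {control: 0.065, tumor: 0.186, tumor_model: C6}
    letrozole: {control: 0.786, tumor: 1.40, tumor_model: C6}
    cisplatin: {control: 0.049, tumor: 0.69, tumor_model: 9L}
  human:
    methotrexate_patient_A: {control: 0.0473, tumor: 0.415}
    methotrexate_patient_B: {control: 0.0473, tumor: 0.451}
    methotrexate_patient_C: {control: 0.0473, tumor: null}
    methotrexate_patient_D: {control: 0.139, tumor: null}
ppa_corrections:
  methotrexate_sham: {estimate: 14.0, applied: true}
  methotrexate_healthy: {estimate: 36.9, applied: true}
  methotrexate_contralateral: {estimate: 49.8, applied: true}
  temozolomide: {estimate: 5.54, applied: true}
  ganciclovir: {estimate: 4.45, applied: true}
  gemcitabine: {estimate: 80.1, applied: true}
  letrozole: {estimate: 0.573, applied: false}
  cisplatin: {estimate: 3.70, applied: false}
  methotrexate_human: {estimate: 892.0, applied: true, note: patient C}
fold_changes:
  cases:
    - {case: methotrexate_RG-2, species: rat, tumor_model: RG-2, pore: 2.66, efflux: 0.392, separately_estimated: true}
    - {case: methotrexate_R-6, species: rat, tumor_model: R-6, pore: 17.2, efflux: 0.804}
    - {case: methotrexate_CNS1, species: rat, tumor_model: CNS1, pore: 7.46, efflux: 0.131}
    - {case: temozolomide_SF188, species: rat, tumor_model: SF188, pore: 0.172, efflux: 0.269}
    - {case: ganciclovir_BT4C, species: rat, tumor_model: BT4C, pore: 2.50, efflux: 0.101}
    - {case: gemcitabine_C6, species: rat, tumor_model: C6, pore: 21.8, efflux: 7.81}
    - {case: letrozole_C6, species: rat, tumor_model: C6, pore: 49.1, efflux: -1.17}
    - {case: cisplatin_9L, species: rat, tumor_model: 9L, pore: 8.12, efflux: 0.0295}
    - case: methotrexate_human
      species: human
      patients:
        A: {pore: 76.0, efflux: 2.62}
        B: {pore: 2210.0, efflux: 54.7}
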