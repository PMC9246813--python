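# Empirical plasma PK models of unbound drug (total drug for temozolomide,
# flagged predicts: total; the CNS coupling multiplies by fup).
# Units: clearances mL/min, volumes mL, rate constants 1/min, lag min.
# IIV standard deviations (omega_*) and the proportional residual SD
# (sigma_prop) are fractions; sigma_add is ng/mL.
version: 1
rat:
  methotrexate_sham:            # sham-brain study arm
    drug: methotrexate
    structure: two_compartment
    cl_cen: 13.3
    q_cen_per: 10.6
    v_cen: 277.0
    v_per: 661.0
    sigma_prop: 0.0899
    sigma_add: 0.0
  methotrexate_healthy:         # healthy-brain study arm, carries IIV
    drug: methotrexate
    structure: two_compartment
    cl_cen: 20.3
    q_cen_per: 4.23
    v_cen: 203.0
    v_per: 80.9
    omega_cl: 0.0567
    omega_v: 0.0
    sigma_prop: 0.0614
    sigma_add: 54.5
  methotrexate_contralateral:   # contralateral-hemisphere study arm
    drug: methotrexate
    structure: two_compartment
    cl_cen: 4.00
    q_cen_per: 1.52
    v_cen: 109.0
    v_per: 163.0
    sigma_prop: 0.107
    sigma_add: 0.0
  temozolomide:
    drug: temozolomide
    structure: one_compartment
    k_el: 0.0129
    v_cen: 233.0
    omega_cl: 0.0657
    omega_v: 0.293
    sigma_prop: 0.0
    sigma_add: 0.0
    predicts: total
  ganciclovir:
    drug: ganciclovir
    structure: one_compartment
    cl_cen: 3.59
    v_cen: 75.9
    k_a: 0.00924
    lag: 19.3
    sigma_prop: 0.0914
    sigma_add: 0.0
  gemcitabine:
    drug: gemcitabine
    structure: two_compartment
    cl_cen: 1.81
    q_cen_per: 5.75
    v_cen: 225.0
    v_per: 140.0
    sigma_prop: 0.0
    sigma_add: 39.2
  letrozole:
    drug: letrozole
    structure: two_compartment
    cl_cen: 7.6
    q_cen_per: 10.0
    v_cen: 378.0
    v_per: 80.0
    sigma_prop: 0.0158
    sigma_add: 30.6
  cisplatin:
    drug: cisplatin
    structure: two_compartment
    cl_cen: 3.11
    q_cen_per: 2.57
    v_cen: 91.2
    v_per: 183.0
    sigma_prop: 0.0584
    sigma_add: 0.0
human:
  methotrexate_patient_A:
    drug: methotrexate_human
    structure: two_compartment
    cl_cen: 163.0
    q_cen_per: 63.2
    v_cen: 20900.0
    v_per: 10400.0
    sigma_prop: 0.107
    sigma_add: 0.0
  methotrexate_patient_B:
    drug: methotrexate_human
    structure: two_compartment
    cl_cen: 174.0
    q_cen_per: 2.78
    v_cen: 27700.0
    v_per: 1670.0
    sigma_prop: 0.0385
    sigma_add: 0.0
  methotrexate_patient_C:
    drug: methotrexate_human
    structure: two_compartment
    cl_cen: 214.0
    q_cen_per: 15.1
    v_cen: 21800.0
    v_per: 3870.0
    sigma_prop: 0.132
    sigma_add: 0.0
  methotrexate_patient_D:
    drug: methotrexate_human
    structure: two_compartment
    cl_cen: 160.0
    q_cen_per: 157.0
    v_cen: 25500.0
    v_per: 7570.0
    sigma_prop: 0.0286
    sigma_add: 45.9
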