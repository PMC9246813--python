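# Tumor pathophysiology rows: the five literature-derived parameters per
# animal model / patient group, with provenance for every derived cell.
#
# "derivations" records how a printed value was obtained from its printed
# sources (rule mean: 3-sig-fig mean of sources; rule scaled_mean:
# scale x mean).  Cells whose underlying sources are not printed (SF188
# f_ecf/ph_ecf) are loaded verbatim and never re-derived.  Human-patient
# rows share tumor volume 50 mL.  Units as in physiology.yaml.
version: 1
rat:
  C6:
    tumor_type: rat glioma
    tumor_volume: 0.03
    f_mv: 2.25
    f_ecf: 24.0
    ph_ecf: 7.16
    ph_icf: 7.28
    cbf_tumor: 2.43
  BT4C:
    tumor_type: rat glioma
    tumor_volume: 0.23
    f_mv: 1.67
    f_ecf: 19.0
    ph_ecf: 7.02
    ph_icf: 7.33
    cbf_tumor: 1.14
    derivations:
      f_ecf: {rule: mean, sources: [13.9, 24.0], note: average of RG-2 and C6}
      ph_ecf: {rule: mean, sources: [6.87, 7.16], note: average of RG-2 and C6}
      ph_icf: {rule: mean, sources: [7.28, 7.37], note: average of C6 and generic rat glioma}
  RG-2:
    tumor_type: rat glioma
    tumor_volume: 0.075
    f_mv: 5.58
    f_ecf: 13.9
    ph_ecf: 6.87
    ph_icf: 7.37
    cbf_tumor: 0.698
    derivations:
      cbf_tumor: {rule: relative, relative: 0.456, note: tumor/control ratio x healthy rat CBF 1.53}
  CNS1:
    tumor_type: rat glioma
    tumor_volume: 0.03
    f_mv: 3.92
    f_ecf: 19.0
    ph_ecf: 7.02
    ph_icf: 7.33
    cbf_tumor: 1.56
    derivations:
      f_mv: {rule: mean, sources: [5.58, 2.25], note: average of RG-2 and C6}
      f_ecf: {rule: mean, sources: [13.9, 24.0], note: average of RG-2 and C6}
      ph_ecf: {rule: mean, sources: [6.87, 7.16], note: average of RG-2 and C6}
      ph_icf: {rule: mean, sources: [7.28, 7.37], note: average of C6 and generic rat glioma}
      cbf_tumor: {rule: mean, sources: [0.698, 2.43], note: average of RG-2 and C6}
  R-6:
    tumor_type: rat rhabdomyosarcoma
    tumor_volume: 0.17
    f_mv: 6.52
    f_ecf: 23.6
    ph_ecf: 6.90
    ph_icf: 7.37
    cbf_tumor: 0.819
    derivations:
      f_mv: {rule: copy, sources: [6.52], note: values of 9L}
      f_ecf: {rule: copy, sources: [23.6], note: values of 9L}
      ph_ecf: {rule: copy, sources: [6.90], note: values of 9L}
      ph_icf: {rule: copy, sources: [7.37], note: values of 9L}
      cbf_tumor: {rule: copy, sources: [0.819], note: values of 9L}
  9L:
    tumor_type: rat gliosarcoma
    tumor_volume: 0.20
    f_mv: 6.52
    f_ecf: 23.6
    ph_ecf: 6.90
    ph_icf: 7.37
    cbf_tumor: 0.819
  SF188:
    tumor_type: human glioma xenograft
    tumor_volume: 0.12
    f_mv: 20.0
    f_ecf: 20.9
    ph_ecf: 6.86
    ph_icf: 7.33
    cbf_tumor: 16.27
    derivations:
      f_mv: {rule: scaled_mean, scale: 4, sources: [4.40, 5.61], note: 4 x average of U251 and U87-MG (highly vascularized line)}
      ph_icf: {rule: mean, sources: [7.28, 7.37], note: average of C6 and generic rat glioma}
      # f_ecf 20.9 and ph_ecf 6.86 are loaded verbatim: labelled an average
      # of U251 and U87-MG, but the underlying source values are not printed.
human:
  patient_A:
    tumor_type: glioblastoma
    tumor_volume: 50.0
    f_mv: 14.9
    f_ecf: 54.9
    ph_ecf: 6.86
    ph_icf: 7.31
    cbf_tumor: 1.31
  patient_B:
    tumor_type: anaplastic astrocytoma
    tumor_volume: 50.0
    f_mv: 15.5
    f_ecf: 52.6
    ph_ecf: 6.75
    ph_icf: 7.31
    cbf_tumor: 1.17
  patient_CD:
    tumor_type: anaplastic oligodendroglioma
    tumor_volume: 50.0
    f_mv: 16.2
    f_ecf: 44.3
    ph_ecf: 6.81
    ph_icf: 7.31
    cbf_tumor: 1.17
    derivations:
      ph_ecf: {rule: mean, sources: [6.86, 6.75], note: average of glioblastoma and anaplastic astrocytoma}
reference_lines:
  # microvasculature fractions of the two human glioma lines used in the
  # SF188 scaling rule, kept for re-derivation
  U87-MG: {f_mv: 5.61, f_ecf: 23.3, ph_ecf: 6.80, cbf_tumor: 0.672}
  U251: {f_mv: 4.40, f_ecf: 13.7, ph_ecf: 6.97}
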