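# Physicochemical records of the six anticancer drugs (flat document:
# MW g/mol, charge class, strongest acidic pKa / basic pKb, logP o/w,
# fraction unbound in plasma).  A missing fup means the paired plasma model
# already describes unbound drug (fup treated as 1).  Cisplatin carries no
# ionization constants and is treated as neutral; its record stands for the
# whole pool of cisplatin-derived free platinum species.
methotrexate:
  mw: 454.45
  charge_class: acid
  pka_acid: 3.41
  pkb_base: 2.81
  logp: -1.85
  fup: 0.448
methotrexate_human:
  mw: 454.45
  charge_class: acid
  pka_acid: 3.41
  pkb_base: 2.81
  logp: -1.85
  fup: 0.677
temozolomide:
  mw: 194.15
  charge_class: neutral
  pka_acid: 10.51
  pkb_base: -3.6
  logp: -1.153
  fup: 0.85
ganciclovir:
  mw: 255.23
  charge_class: neutral
  pka_acid: 10.16
  pkb_base: 1.76
  logp: -1.66
  fup: null
gemcitabine:
  mw: 263.20
  charge_class: neutral
  pka_acid: 11.52
  pkb_base: 3.65
  logp: -1.4
  fup: null
letrozole:
  mw: 285.30
  charge_class: neutral
  pka_acid: null
  pkb_base: 2.17
  logp: 2.5
  fup: 0.38
cisplatin:
  mw: 300.05
  charge_class: neutral
  pka_acid: null
  pkb_base: null
  logp: -2.19
  fup: null
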