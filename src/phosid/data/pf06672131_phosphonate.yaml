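# Default probe definition: the PF-06672131 (alkynylated afatinib derivative)
# phosphonate adduct left on a cysteine after click attachment of the handle.
# Human-editable; masses in Da, m/z for singly charged ions.
name: PF-06672131-phosphonate
adduct_formula: C29H34N9O6ClFP
adduct_mass: 689.20422
target_residue: C
# Hydrogen-atom mass: the printed diagnostic-ion values are consistent with
# adding the H atom (1.007825) rather than the proton (1.007276); the 0.00055 Da
# difference is the electron mass.
charge_carrier_mass: 1.00782503207
diagnostic_ions:
  - 194.05822
  - 247.08477
  - 690.21205
  - 416.12896
  - 645.15
  - 724.20
# Ions known only to 2-decimal precision (645.15, 724.20) and the MS1-level
# species below are kept at printed precision and excluded from the
# self-consistency check, which needs sub-mDa values.
checked_diagnostic_ions:
  - 194.05822
  - 247.08477
  - 690.21205
  - 416.12896
ms1_species:
  - 690.21
  - 663.13
  - 645.15
  - 416.13
neutral_losses:
  - 274.08309
  - 292.09366
  - 689.20422
trigger_ions:
  - 194.05822
  - 247.08477
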