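# Physicochemical and biological properties of the ten benchmark drugs.
# Ionization constants outside [2, 12] are retained for the record but are
# treated as non-ionizable at physiological pH by the neutral-fraction model.
#
# p_trans_cm_min values are NOT measurements: they come from the clearly
# labelled placeholder estimator log10(P_trans) = -3.5 + 0.4*logP (cm/min)
# and exist only so that fixture-mode simulations run end to end. Replace
# with measured passive transcellular permeabilities for real use.
drugs:
  cyclophosphamide:
    mwt: 261.0
    logp: 0.76
    pka_acid: [13.48]
    pka_base: []
    hba: 1
    hbd: 1
    psa: 41.57
    fu_plasma: 0.26
    kpuu_bbb: 0.339
    kpuu_method: estimated
    p_trans_cm_min: 6.37e-4
  quinidine:
    mwt: 324.0
    logp: 2.82
    pka_acid: [13.89]
    pka_base: [9.05]
    hba: 4
    hbd: 1
    psa: 45.59
    fu_plasma: 0.233
    kpuu_bbb: 0.2185
    kpuu_method: literature
    p_trans_cm_min: 4.25e-3
  erlotinib:
    mwt: 393.0
    logp: 3.13
    pka_acid: [16.14]
    pka_base: [4.62]
    hba: 7
    hbd: 1
    psa: 74.73
    fu_plasma: 0.048
    kpuu_bbb: 0.628
    kpuu_method: estimated
    p_trans_cm_min: 5.65e-3
  phenobarbital:
    mwt: 232.0
    logp: 1.4
    pka_acid: [7.14]
    pka_base: []
    hba: 3
    hbd: 2
    psa: 75.27
    fu_plasma: 0.7
    kpuu_bbb: 0.0121
    kpuu_method: estimated
    p_trans_cm_min: 1.15e-3
  colchicine:
    mwt: 399.0
    logp: 1.59
    pka_acid: [15.06]
    pka_base: [-1.2]
    hba: 6
    hbd: 1
    psa: 83.09
    fu_plasma: 0.61
    kpuu_bbb: 0.14
    kpuu_method: literature
    p_trans_cm_min: 1.37e-3
  ribociclib:
    mwt: 435.0
    logp: 2.5
    pka_acid: [11.59]
    pka_base: [8.87]
    hba: 7
    hbd: 2
    psa: 91.21
    fu_plasma: 0.23
    kpuu_bbb: 0.0693
    kpuu_method: literature
    p_trans_cm_min: 3.16e-3
  topotecan:
    mwt: 421.0
    logp: 1.84
    pka_acid: [8.0]
    pka_base: [9.75]
    hba: 6
    hbd: 2
    psa: 103.2
    fu_plasma: 0.3
    kpuu_bbb: 0.21
    kpuu_method: literature
    p_trans_cm_min: 1.72e-3
  cefadroxil:
    mwt: 363.0
    logp: 0.51
    pka_acid: [3.25]
    pka_base: [7.22]
    hba: 6
    hbd: 4
    psa: 132.96
    fu_plasma: 1.0
    kpuu_bbb: 0.05
    kpuu_method: estimated
    p_trans_cm_min: 5.06e-4
  prexasertib:
    mwt: 365.0
    logp: 1.77
    pka_acid: [10.02]
    pka_base: [9.85]
    hba: 8
    hbd: 3
    psa: 134.76
    fu_plasma: 0.11
    kpuu_bbb: 0.09
    kpuu_method: literature
    p_trans_cm_min: 1.61e-3
  methotrexate:
    mwt: 454.0
    logp: -0.91
    pka_acid: [3.41]
    pka_base: [2.81]
    hba: 12
    hbd: 6
    psa: 205.92
    fu_plasma: 0.519
    kpuu_bbb: 0.195
    kpuu_method: estimated
    p_trans_cm_min: 1.37e-4
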