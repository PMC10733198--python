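# Default mouse CNS physiology. Literature values are kept alongside the
# aggregation rule that produced each final value; `derived` parameters are
# recomputed from their derivation formula at load time.
#
# Units as declared per parameter; the registry converts to canonical units
# (ml, ml/min, cm^2, cm) on access.
name: mouse_default
species: mouse
parameters:
  V_brain_total:
    unit: ul
    aggregation: median
    literature_values: [303, 360, 495, 150, 350, 360, 360]
  V_ECF:
    unit: ul
    aggregation: single
    literature_values: [67]
  V_ICF:
    unit: ul
    aggregation: derived
    derivation: icf_from_total_brain
  V_LYS_total:
    unit: ul
    aggregation: derived
    derivation: lysosome_from_icf
  V_CSF_total:
    unit: ul
    aggregation: single
    literature_values: [35]
  V_ventricles_total:
    unit: ul
    aggregation: single
    literature_values: [4.8]
  V_LV:
    unit: ul
    aggregation: printed
    final_value: 4.0
    literature_values: [1.0275, 0.4, 2.0, 0.79, 0.32, 0.46, 0.12, 0.13]
    note: >
      Final value taken from the source compilation; the listed per-study
      sub-values average to ~0.67 ul. The discrepancy is surfaced as a soft
      validation warning rather than resolved.
  V_TFV:
    unit: ul
    aggregation: single
    literature_values: [2.5]
  V_CM:
    unit: ul
    aggregation: single
    literature_values: [2.13]
    note: scaled assuming equal CSF partitioning ratios between rat and mouse
  V_SAS:
    unit: ul
    aggregation: single
    literature_values: [16.88]
    note: scaled assuming equal CSF partitioning ratios between rat and mouse
  V_MV:
    unit: ul
    aggregation: single
    literature_values: [5]
  Q_CBF:
    unit: ml/min
    aggregation: mean
    literature_values: [0.46134, 0.46134]
  Q_ECF:
    unit: ml/min
    aggregation: mean
    literature_values: [0.0001248, 0.000624]
    note: second value scaled to a 0.416 g mouse brain
  Q_CSF:
    unit: ml/min
    aggregation: mean
    literature_values: [0.000325, 0.000361]
    note: >
      The 0.000361 entry is the volume-turnover estimate
      (0.040 ml CSF x 13 turnovers/day / 1440 min/day); the aggregate of the
      two entries is the printed 0.000343.
  SA_BBB:
    unit: cm^2
    aggregation: mean
    literature_values: [18.78, 20.74]
    note: >
      18.78 from regional surface-per-volume weighted by regional volumes;
      20.74 from microvessel radius and length density.
  SA_BCSFB:
    unit: cm^2
    aggregation: derived
    derivation: bcsfb_half_bbb
  SA_BCM:
    unit: cm^2
    aggregation: derived
    derivation: cell_membrane_spheres
  SA_LYS:
    unit: cm^2
    aggregation: single
    literature_values: [540]
    note: >
      Stated to derive from lysosomal radius and total lysosome volume, but
      the radius is not reported; stored as a literal.
  f_trans_BBB:
    unit: unitless
    aggregation: single
    literature_values: [0.998]
  f_trans_BCSFB:
    unit: unitless
    aggregation: single
    literature_values: [0.998]
  f_para_BBB:
    unit: unitless
    aggregation: single
    literature_values: [0.006]
  f_para_BCSFB:
    unit: unitless
    aggregation: single
    literature_values: [0.05]
  w_BBB:
    unit: um
    aggregation: single
    literature_values: [0.7]
  w_BCSFB:
    unit: um
    aggregation: single
    literature_values: [1.7]
  f_phospholipid:
    unit: unitless
    aggregation: single
    literature_values: [0.05]
  pH_plasma:
    unit: pH
    aggregation: single
    literature_values: [7.4]
  pH_ECF:
    unit: pH
    aggregation: single
    literature_values: [7.4]
  pH_ICF:
    unit: pH
    aggregation: single
    literature_values: [7.2]
  pH_LYS:
    unit: pH
    aggregation: printed
    final_value: 5.5
    literature_values: [4.8, 5.5, 6.0, 5.5, 5.6, 4.9]
    note: >
      Final value taken as printed; the six cell-type-specific literature
      values (neurons, microglia, astrocytes) average to ~5.38. Surfaced as a
      soft validation warning.
  pH_CSF:
    unit: pH
    aggregation: single
    literature_values: [7.2]
  N_cells:
    unit: count
    aggregation: single
    literature_values: [108690000]
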