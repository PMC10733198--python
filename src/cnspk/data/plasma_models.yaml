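# Compartmental plasma PK parameter sets for the ten benchmark drugs,
# used as forcing-function inputs and as population-simulation fixtures.
#
# Conventions:
#   - ka = 0 with an extravascular route means absorption was not modelled
#     kinetically; the dose enters the central compartment directly.
#   - zero_order_duration > 0 imposes zero-order release of the dose over
#     that window before any first-order absorption.
#   - iiv entries are variances of exponential (lognormal) random effects;
#     omitted parameters have no interindividual variability.
#   - residual: prop_var is the proportional-error variance, add_var the
#     additive-error variance (ng/ml scale).
models:
  cyclophosphamide:
    n_compartments: 2
    route: IP
    dose_mg_kg: 130
    fu_plasma: 0.26
    CL: 2.09
    Q2: 0.086
    Vc: 18.5
    Vp2: 1.77
    ka: 0.0
    zero_order_duration: 0.0
    iiv: {CL: 0.012}
    residual: {prop_var: 0.058, add_var: 0.0}
  quinidine:
    n_compartments: 1
    route: IP
    dose_mg_kg: 40
    fu_plasma: 0.233
    CL: 46.99
    Vc: 3295.0
    ka: 2.61
    zero_order_duration: 10.0
    iiv: {}
    residual: {prop_var: 0.0, add_var: 2.05}
  erlotinib:
    n_compartments: 1
    route: PO
    dose_mg_kg: 50
    fu_plasma: 0.048
    CL: 0.412
    Vc: 1.31
    ka: 0.012
    zero_order_duration: 10.0
    iiv: {ka: 0.614}
    residual: {prop_var: 0.212, add_var: 0.0}
  phenobarbital:
    n_compartments: 1
    route: IP
    dose_mg_kg: 10
    fu_plasma: 0.7
    CL: 0.02
    Vc: 47.0
    ka: 0.0
    zero_order_duration: 0.0
    iiv: {}
    residual: {prop_var: 0.005, add_var: 0.0}
  colchicine:
    n_compartments: 2
    route: IV
    dose_mg_kg: 1.5
    fu_plasma: 0.61
    CL: 0.487
    Q2: 2.11
    Vc: 11.27
    Vp2: 705.0
    ka: 0.0
    zero_order_duration: 0.0
    iiv: {}
    residual: {prop_var: 0.0224, add_var: 0.0}
  ribociclib:
    n_compartments: 1
    route: PO
    dose_mg_kg: 100
    fu_plasma: 0.23
    CL: 1.32
    Vc: 0.15
    ka: 0.046
    zero_order_duration: 0.0
    iiv: {CL: 0.217, ka: 0.676}
    residual: {prop_var: 0.276, add_var: 0.0}
  topotecan:
    n_compartments: 2
    route: IV
    dose_mg_kg: 4
    fu_plasma: 0.3
    CL: 1.41
    Q2: 0.486
    Vc: 30.1
    Vp2: 18.36
    ka: 0.0
    zero_order_duration: 0.0
    iiv: {CL: 0.011}
    residual: {prop_var: 0.051, add_var: 0.0}
  cefadroxil:
    n_compartments: 1
    route: IV
    dose_mg_kg: 36
    fu_plasma: 1.0
    CL: 0.97
    Vc: 8.41
    ka: 0.0
    zero_order_duration: 0.0
    iiv: {}
    residual: {prop_var: 0.0, add_var: 0.0}
  prexasertib:
    n_compartments: 2
    route: SC
    dose_mg_kg: 10
    fu_plasma: 0.11
    CL: 2.68
    Q2: 0.276
    Vc: 1451.59
    Vp2: 97.47
    ka: 0.018
    zero_order_duration: 0.0
    iiv: {CL: 0.046, Q2: 0.027, ka: 0.04}
    residual: {prop_var: 0.003, add_var: 0.0}
  methotrexate:
    n_compartments: 2
    route: IV
    dose_mg_kg: 1000
    fu_plasma: 0.519
    CL: 0.688
    Q2: 0.03
    Vc: 9.21
    Vp2: 2.14
    ka: 0.0
    zero_order_duration: 0.0
    iiv: {CL: 0.021}
    residual: {prop_var: 0.18, add_var: 0.0}
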