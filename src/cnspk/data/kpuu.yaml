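# Unbound brain-ECF/plasma steady-state partition coefficients at the BBB.
# method: "estimated" = obtained by fitting influx/efflux clearances of a
# one-compartment brain model on top of the plasma PK model;
# "literature" = reported value.
kpuu_bbb:
  cyclophosphamide: {value: 0.339, method: estimated}
  quinidine: {value: 0.2185, method: literature}
  erlotinib: {value: 0.628, method: estimated}
  phenobarbital: {value: 0.0121, method: estimated}
  colchicine: {value: 0.14, method: literature}
  ribociclib: {value: 0.0693, method: literature}
  topotecan: {value: 0.21, method: literature}
  cefadroxil: {value: 0.05, method: estimated}
  prexasertib: {value: 0.09, method: literature}
  methotrexate: {value: 0.195, method: estimated}
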