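# cnspk

A mouse CNS physiologically-based pharmacokinetic (PBPK) modelling toolkit.
It predicts unbound drug concentration–time profiles in brain extracellular
fluid (and the other CNS compartments) from three ingredients:

1. a **mouse CNS physiology registry** (volumes, flows, surfaces, pH values,
   with literature values, aggregation rules and derivation formulas),
2. a **compartmental plasma PK model** used as a forcing function, and
3. a **Kp,uu,BBB value** converted into blood–brain-barrier asymmetry
   factors that encode net active transport.

Around the simulator it provides the full study workflow: pooled
maximum-likelihood plasma model fitting, Kp,uu estimation by AUC-ratio or by
fitting BBB influx/efflux clearances, prediction-performance metrics
(%AFE, %AAFE, fold-error classification, VPC bands), and a synthetic
microdialysis-study generator with known ground truth so that every stage is
testable end to end.

## Layout

| Module | Contents |
| --- | --- |
| `cnspk.physiology` | parameter registry, aggregation, derivations, validation |
| `cnspk.drugs` | drug records, neutral fraction, cell binding, paracellular permeability |
| `cnspk.plasma` | 1–3 compartment models, exact linear solver, simulation with IIV/residual error, pooled ML fitting, forcing functions |
| `cnspk.bbb` | Kp,uu estimation (AUC ratio, clearance ratio) and asymmetry factors |
| `cnspk.cns` | the CNS PBPK ODE system (microvasculature, ECF, ICF, lysosomes, CSF cascade), simulation and direct steady-state solves |
| `cnspk.evaluation` | %AFE / %AAFE, two-/five-fold classification, VPC percentile bands |
| `cnspk.synthetic` | synthetic study designs, interval-averaged microdialysis sampling |
| `cnspk.pipeline` / `cnspk.cli` | end-to-end orchestration and the `cnspk` command |

Packaged fixture data (`src/cnspk/data/`): the default mouse physiology
registry, physicochemical/biological records for the ten benchmark drugs,
their plasma PK parameter sets, and their Kp,uu,BBB values.

## CLI

```sh
cnspk simulate --drug topotecan --t-end 1440 --out-dir out/
cnspk generate --drug cefadroxil --n-animals 8 --seed 1 \
    --obs-out obs.csv --dose-out doses.csv --truth-out truth.yaml
cnspk fit-plasma --obs obs.csv --doses doses.csv --route IV --out fit.yaml
cnspk estimate-kpuu --obs obs.csv --doses doses.csv --drug cefadroxil \
    --method clearance_ratio --out kpuu.json
cnspk evaluate --pred out/<hash>/topotecan_profiles.csv \
    --obs obs.csv --doses doses.csv --out metrics.json
cnspk run --config config.yaml
```

`cnspk run` executes physiology → plasma forcing → Kp,uu/asymmetry factors →
CNS simulation → evaluation, writing tidy profile CSVs, a deterministic
`metrics.json` and a run log under `out_dir/<config-hash>/`.

## Notes on conventions

- Units are canonicalised internally to ml, ng, min and cm²; fixture files
  declare their own units (µl, µm) and are converted on load.
- Transcellular permeation acts on the neutral species only; paracellular
  permeation acts on all unbound species and is symmetric. Kp,uu < 1 scales
  the efflux clearance (AF_out = 1/Kp,uu), Kp,uu > 1 the influx clearance.
- Extravascular doses with no absorption rate constant (ka = 0) enter the
  central compartment directly (absorption treated as fast relative to
  sampling), matching how several fixture models are parameterised.
- Plasma fitting is pooled (naive-pooled) maximum likelihood on typical
  values; interindividual variability is used in simulation only.
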