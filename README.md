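# pksymreg

Symbolic-regression discovery of pharmacometric covariate model structures.

`pksymreg` learns human-readable closed-form expressions that map patient
covariates (age, weight, BMI, gender, blood-sampling site) to the parameters
of a three-compartment pharmacokinetic model. Small *symbolic-regression
networks* — affine layers whose activations are algebraic base expressions
(identity, product, power, guarded division, absolute value) — are trained
end-to-end through an exact, differentiable PK simulator against a median
absolute logarithmic error loss, then sparsified by Hessian-salience
(optimal-brain-damage style) pruning until a short readable formula remains.

## Components

| module | what it does |
| --- | --- |
| `pksymreg.pk_model` | exact LTI simulation of the mammillary three-compartment model under piecewise-constant infusion (matrix exponential per inter-event interval; eigendecomposition fast path), parameter conversions, complex-step sensitivities |
| `pksymreg.error_metrics` | per-sample LE/ALE/PE/APE, per-individual medians, the population loss J_ALE, clinical acceptability bounds (0.18 / 0.34) |
| `pksymreg.symreg_network` | covariate normalization, the pruned-affine-layer networks (one per PK parameter), hand-coded backprop, JSON serialization |
| `pksymreg.training_pruning` | ADAM training through the simulator, parameter/covariate salience via loss Hessian diagonals, the 11-step train/prune recipe, multi-restart, k-fold cross-validation |
| `pksymreg.expression_export` | network → expression-tree extraction (guard-exact), interval-arithmetic abs-elimination, text/LaTeX rendering with a round-trip parser, the published propofol covariate model as an executable fixture |
| `pksymreg.baselines` | covariate-free performance limits: one shared parameter set (lower limit) and per-individual fits (upper limit) |
| `pksymreg.synthetic_data` | synthetic cohorts (study-range covariates, step infusions, lognormal observation noise), dose-merge preprocessing (1 s / 0.5 µg/s) |
| `pksymreg.interface` | CSV dataset dialect, reader/writer, CLI |

## CLI

```bash
# synthetic cohort from the published covariate model, sigma = 0.15
pksymreg generate --seed 7 --n 100 --out-dir out

# multi-restart train/prune recipe -> bank.json + expressions + manifest
pksymreg fit out/dataset.csv --seed 1 --restarts 8 --out-dir out

# error table (mean MdALE / MdLE / MdAPE / MdPE) for a bank or the
# published model
pksymreg evaluate out/dataset.csv --bank out/bank.json --out-dir out

# performance-limit baselines
pksymreg baselines out/dataset.csv --out-dir out

# render expressions from a fitted bank
pksymreg export out/bank.json --format latex --out-dir out

# simulate a concentration profile
pksymreg simulate --rates '{"k10":0.005,"k12":0.05,"k13":0.01,"k21":0.04,"k31":0.008,"V1":10}' \
    --dose-times 0,10,1200 --dose-rates 20000,120,0 --obs-times 60,600,3000
```

Units: time s, infusion rate µg/s, concentration µg/L, volume L.

## Data format

One CSV row per event (`# pksymreg-csv v1` header):

```
id,time_s,rate_ugps,conc_ugpl,age_y,wgt_kg,bmi,gender,site
A,0,20000,,30,70,24,M,A      # dose row: rate set, concentration empty
A,120,,3.5,30,70,24,M,A      # observation row: concentration set
```

Covariates repeat on every row and must be constant within an individual;
gender is M/F, sampling site is A (arterial) / V (venous). On ingestion,
consecutive dose events closer than 1 s or differing by less than 0.5 µg/s
are merged (disable with `--no-merge`).
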