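# semiquant

**Semi-quantitative drug concentration estimation in whole blood from
LC-HRMS screening signals and molecular structure.**

When a rarely encountered or newly emerging drug is tentatively identified
in a forensic blood screen, the toxicologist must decide whether it could be
present at a toxic level — but quantification normally requires a reference
standard that may take weeks to source. `semiquant` addresses this gap: it
learns the relationship between a molecule's structure and its
signal-to-concentration ratio from matrix-matched spiked calibration data,
then converts a measured, internal-standard-corrected peak area directly
into a concentration estimate, no reference standard required.

## The model

For molecule *m* spiked at concentration *c<sub>m</sub>* (mg/kg) with
analyte peak area *s<sub>m</sub>* and internal-standard area
*s*<sub>ISTD</sub>:

```
s̄_m = s_m / s_ISTD                 ISTD-corrected area
α_m = s̄_m / c_m                    signal-to-concentration ratio
β_m = ln ᾱ_m                       regression target (ᾱ averaged over the
                                   dilution series, ±0.5ᾱ outliers removed)
```

A graph attention network (4 single-head GAT layers, 28 channels, tanh;
5 layers for ionization-efficiency targets) maps the heavy-atom molecular
graph — with 12 atomic features plus 4 global 3D shape features per node —
to a per-node value, pooled to β̂ by average pooling or a positional
(first/second/last SMILES atom) readout. Descriptor-based baselines (MLP,
decision tree, random forest with the canonical hyperparameters) and
leave-one-out / 5-fold / subset-LOOCV harnesses are included. A prediction
is scored correct when |β̂ − β| < t with t = ln 2, which is exactly the
condition for the concentration estimate

```
ĉ = s̄ / exp(β̂)
```

to fall within a factor of two of the truth. The network and its gradients
are implemented in NumPy (full-batch RMSprop, bitwise reproducible per
seed); see `docs/methods.md` for every numerical convention.

## Worked example

Simulate a spiking study, recover β by preprocessing, cross-validate the
GNN, and invert a signal into a concentration:

```python
import numpy as np
import semiquant as sq

# a 60-molecule spiking study: 7-level factor-2 dilution ladder,
# 10% multiplicative signal noise, 2% injected outliers
spec = sq.SyntheticSpec(n_molecules=60, signal_noise_cv=0.1,
                        beta_noise_sd=0.1, outlier_fraction=0.02, seed=0)
study = sq.simulate_study(spec)

prep = sq.preprocess_measurements(study.measurements)
beta = {b.molecule_id: b.beta for b in prep.beta_records}

graphs = [sq.featurize_smiles(m.smiles, m.molecule_id) for m in study.molecules]
y = np.array([beta[m.molecule_id] for m in study.molecules])

report = sq.run_cv(graphs, y, sq.GNNConfig(seed=0),
                   sq.CVPlan(scheme="kfold", k=5, split_seed=42, n_repeats=2))
print(report)
```

```
Cross-Validation Report
============================================
Scheme:       kfold (k=5)
Molecules:    60   Repeats: 2
Accuracy (t=0.6931): 94.2 ± 5.9 %
MAE:          0.282 ± 0.070
MSE:          0.135 ± 0.061
============================================
```

94% of held-out molecules have β̂ within ±ln 2 of truth, i.e. their
concentrations would be estimated between 50% and 200% of the spiked value;
MAE is on the natural-log scale of α. Inverting a measured signal:

```python
c_hat = sq.estimate_concentration(beta_hat=2.1, s_bar=0.65)
# 0.0796  -> a 0.08 mg/kg estimate; the true value lies in
#            0.04–0.16 mg/kg whenever the β error is within ln 2
```

The same workflow is available from the shell:

```bash
semiquant simulate   --config cfg.yaml --out-dir sim/
semiquant preprocess --measurements sim/measurements.csv --out-dir prep/
semiquant cv         --molecules sim/molecules.csv --config cfg.yaml --out-dir cv/
semiquant train      --molecules sim/molecules.csv --config cfg.yaml --out model.json
semiquant predict    --model model.json --molecules sim/molecules.csv --out preds.csv
semiquant estimate   --input signals.csv --out estimates.csv
```

Every command writes a resolved-configuration YAML and a log file next to
its outputs; every CSV carries a schema-version header comment.

To train on real data, supply a measurements CSV
(`sample_id, molecule_id, smiles, concentration_mg_per_kg, area, istd_area`)
or a molecules CSV with precomputed targets, and optionally a
PaDEL-export descriptor table for the non-graph baselines.

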