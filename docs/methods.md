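# Methods

`semiquant` estimates the concentration of a drug in whole blood from an
LC-HRMS screening signal without a reference standard. The package covers
the full workflow: turning spiked-sample measurements into per-molecule
response factors, learning those response factors from molecular structure,
validating the models, and inverting a measured signal into a concentration
estimate.

## Model

For a molecule *m* spiked at concentration *c<sub>m</sub>* (mg/kg), the
instrument reports an analyte peak area *s<sub>m</sub>* and an internal
standard area *s*<sub>ISTD</sub>. The ISTD-corrected area is
*s̄<sub>m</sub> = s<sub>m</sub>/s*<sub>ISTD</sub>, and the
signal-to-concentration ratio (per-molecule response factor) is

> α<sub>m</sub> = s̄<sub>m</sub> / c<sub>m</sub>.

α spans several orders of magnitude across drug-like molecules, so the
regression target is its natural log, β<sub>m</sub> = ln ᾱ<sub>m</sub>,
where ᾱ<sub>m</sub> averages α over the dilution series. Given a predicted
β̂ for a newly encountered molecule and a measured s̄, the concentration
estimate is ĉ = s̄ / exp(β̂). By construction, |β̂ − β| ≤ ln 2 if and only
if ĉ is within a factor of two of the true concentration; the headline
"accuracy" metric *A* is therefore the fraction of molecules with
|β̂ − β| < t at t = ln 2 (strict inequality; a deviation of exactly t counts
as incorrect). t = ln 2 also equals the smallest log-spacing of the default
dilution ladder, so finer agreement would be below the design resolution of
the calibration experiment.

## Preprocessing

α is computed per measurement and averaged per molecule. Outliers of the
linear range are removed with a single-pass relative filter: the mean ᾱ is
computed over *all* values, any value deviating by more than ±0.5·ᾱ
(strictly) is removed, and the mean is recomputed once. Single-pass
semantics (rather than iterating to a fixed point) is a deliberate choice:
it is auditable, order-independent, and sufficient for dilution series where
at most one or two points leave the linear range. Both the pre- and
post-removal means are retained; the post-removal mean is canonical. If the
filter would remove everything, all values are kept and a warning is
emitted. There is no automatic "unreasonable value" detection: molecules or
samples known to be compromised (blank contamination, matrix interference)
are removed only through an explicit, logged exclusion list. Rows with zero
area produce α = 0, violate positivity, and land in a rejects table with a
reason code.

## Featurization

The graph model consumes the heavy-atom graph (hydrogens implicit, bond
types deliberately not encoded — only connectivity) with 16 features per
node: 12 local atomic descriptors (atomic number, hydrogen count, valence
electrons, radical electrons, formal charge, hybridization code, heavy-atom
degree, ring flag, aromatic flag, and scaled van der Waals radius, atomic
mass, covalent radius) and 4 global shape descriptors copied onto every node
(conformer volume, width, length, height). Copying global values onto nodes
lets a node-level network read molecule-level size information that softmax
attention aggregation would otherwise struggle to recover.

Numerical conventions:

* **Scaling constants.** The three scaled columns are divided by the maxima
  of the tabulated values over elements H–Rn: van der Waals radius 3.00 Å,
  atomic mass 222.0 u, covalent radius 2.44 Å (RDKit periodic table;
  constants are computed at import and exposed as
  `featurize.VDW_RADIUS_SCALE` etc.).
* **Hybridization code.** unspecified→0, sp→1, sp²→2, sp³→3, sp³d→4,
  sp³d²→5, anything else→6. A single integer column (not one-hot) keeps
  exactly 12 local columns.
* **3D protocol.** One ETKDGv3 conformer with a fixed random seed (retries
  with shifted seeds and random-coordinate initialization on embedding
  failure), MMFF94 relaxation (UFF fallback). Extents are coordinate ranges
  of the heavy-atom centers along the principal axes of the centered
  coordinate cloud, sorted descending into length ≥ width ≥ height. Volume
  is the union of heavy-atom van der Waals spheres with inclusion–exclusion
  truncated at pair overlaps; it depends only on interatomic distances and
  radii and is therefore exactly invariant under rigid motion (a grid-based
  volume would not be). Principal-axis extents are rotation-invariant
  whenever the covariance spectrum is non-degenerate; for exactly symmetric
  tops (e.g. an isolated benzene) the in-plane axes are arbitrary — a known
  and documented limitation.
* **Disconnected SMILES** (salts, mixtures): the largest fragment is kept
  and the event logged. Explicit-hydrogen SMILES are normalized to the
  heavy-atom graph.

Descriptor-based baselines consume a molecule × descriptor table. The
canonical path is importing a precomputed table (PaDEL-export dialect:
`Name` id column, header row of descriptor names; empty/NA cells imputed
with the column median and flagged, constant columns retained but flagged);
a small graph-derived count-descriptor generator is included for
self-contained work. Reduction to the "main features" ranks descriptors by
random-forest mean impurity decrease (the same 500-tree depth-4 forest used
for regression), with ties broken by name; 11 features is the default
compromise. By default the selection is re-run inside each cross-validation
training fold (strict leak avoidance); a flag switches to one global list,
which is what a fixed published feature table implies, at the cost of mild
selection leakage — both modes are logged.

## Graph attention regressor

A stack of single-head graph attention (GAT) layers, 28 channels each, tanh
activations; 4 layers for β, 5 for ionization-efficiency-style targets. Each
undirected bond is presented as two directed edges, plus one self-loop per
node; attention is a per-destination softmax over LeakyReLU(slope 0.2) pair
scores. The final layer is a linear per-node head, giving one value per
node; a readout reduces node values to a molecular prediction: average
pooling (default) or the node at the first/second/last position of the
SMILES chain (the second-node mode falls back to the first node with a
warning on single-atom molecules). Positional readouts always use SMILES
parse order, never a canonical reordering.

The network and its gradients are implemented directly in NumPy (the
backward pass is verified against finite differences in the test suite).
Training is full-batch RMSprop (decay 0.9, ε = 1e-8) on a mean-squared-error
loss, learning rate 1e-3, 1000 epochs by default — convergence on the data
sizes this package targets (hundreds of molecules) plateaus well before
that, and the loss trajectory is recorded per epoch. Node features are
standardized column-wise with training-set statistics stored on the fitted
model. Glorot-uniform initialization from a seeded generator makes training
bitwise reproducible on a fixed platform. Because RMSprop rescales steps
adaptively, the loss trajectory shows occasional transient upticks of order
1e-3; the monotonicity property enforced in tests is the honest version
(finite everywhere, bounded transients, strict decrease across coarse
strides). Repeated-run spreads are obtained by retraining with five
consecutive seeds and reporting mean ± sample standard deviation.

## Baselines

MLP (hidden layers 500-400-300-200-100, ReLU, Adam, MSE, inputs
standardized with training-fold statistics only), decision tree
(squared-error criterion, depth 4, min split 2), and random forest (500
estimators, depth 4). Trees and forests see raw features — standardization
is immaterial to axis-aligned splits. Targets are never standardized (β is
already log-scaled). The MLP iteration budget defaults to 2000 with no early
stopping; all hyperparameters are exposed in `BaselineConfig`.

## Validation harnesses

Leave-one-out, 5-fold (non-stratified random splits, split seed 42 held
fixed across repeats), and subset-LOOCV (a fresh random subset of 25/50/75/
100% per repeat, leave-one-out within it). Metrics are pooled over
out-of-fold predictions — LOOCV forces pooling, so k-fold pools too for
comparability — and reported as mean ± SD over repeats with fresh model
seeds. Every fold records the SHA-256 of its training ids, targets, and
feature bytes, so test-fold isolation (including feature selection and MLP
standardization) is verifiable after the fact, not just asserted.

## Synthetic data generator

The generator emulates a decision-point spiking experiment so the whole
pipeline is testable offline:

* **Molecules** come from a deterministic grammar (linear/branched alkanes
  with terminal O/N/F/Cl/Br groups; mono- and para-disubstituted benzenes),
  deduplicated by canonical SMILES — every string parses, every test is
  reproducible, and no data files ship with the package.
* **β rule**: β_true = 0.4·(heavy atoms) − 0.1·(aromatic atoms) +
  0.8·1{contains N} + ε, ε ~ N(0, 0.1²) by default. A linear rule in
  graph-computable counts is learnable by both model families and spans
  roughly three orders of magnitude in α over the grammar's size range,
  so parameter recovery is a meaningful end-to-end check.
* **Measurements**: seven concentration levels in a factor-2 serial dilution
  from 0.1 mg/kg (range ≈ 0.0016–0.1 mg/kg, matching typical forensic
  spiking ranges; smallest log-spacing exactly ln 2), one shared ISTD area
  per sample (lognormal around 1e5 counts, 5% spread — it cancels exactly in
  α, as in the real workflow), multiplicative signal noise with CV 0.1.
* **Outliers** are one-sided multiplicative perturbations by (1 + offset),
  offset 0.8 by default, injected into at most one dilution row per
  molecule. The one-per-molecule restriction is what makes recovery exact:
  with seven levels and a single perturbed row, an offset of 0.8 always
  exceeds the ±0.5·ᾱ band while every clean row stays inside it; two
  outliers in one seven-point series could mask each other below the
  single-pass threshold.

What the generator does **not** emulate: matrix effects, adduct chemistry,
isotope patterns, ionization suppression, heteroscedastic noise across the
calibration range, or the structural diversity of real drug libraries. A
passing parameter-recovery test shows the pipeline is correct and the models
can learn a structure-determined response factor at realistic noise levels —
it does not certify accuracy on real whole-blood data, where the
structure→β relationship is far harder than the synthetic rule.

## Default study sizes

Tests and the acceptance script use 200 molecules for parameter recovery
(5-fold CV, five model seeds) and 25–100 molecules for exactness checks —
large enough for stable statistics while keeping a full run in minutes on a
single CPU. The same code paths scale unchanged to larger libraries.

## Known limitations

* Principal-axis extents are ambiguous for exactly symmetric conformers
  (degenerate covariance spectra).
* The pairwise-truncated sphere-union volume ignores triple overlaps and
  hydrogen contributions; it is a consistent, rotation-invariant size proxy
  rather than a calibrated molecular volume.
* Single-head attention and full-batch training are chosen for determinism
  and small-data stability, not throughput; the implementation is not
  intended for datasets beyond a few thousand molecules.
* The exclusion-list mechanism deliberately refuses to guess which
  measurements are "unreasonable"; that judgement stays with the analyst.
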