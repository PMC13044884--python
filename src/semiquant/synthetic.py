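"""Synthetic molecules, β targets, and spiked-dilution measurement tables.

Everything downstream of the instrument is testable without any download:

* :func:`generate_molecules` draws distinct, always-parseable SMILES from a
  small deterministic grammar (linear and branched alkanes with terminal
  O/N/halogen groups, mono- and para-disubstituted benzenes).
* :func:`assign_beta` gives each molecule a ground-truth log
  signal-to-concentration ratio that is a fixed linear function of
  graph-computable counts plus Gaussian noise, so both descriptor models and
  the graph network can learn it and parameter recovery is verifiable:

  ``β_true = 0.4·n_heavy − 0.1·n_aromatic + 0.8·1{contains N} + ε``,
  ``ε ~ N(0, noise_sd²)``.

* :func:`generate_measurements` inverts the preprocessing model: for each
  molecule and spiked concentration level ``c`` it emits an analyte area
  ``s = exp(β_true)·c·s_ISTD·(1 + δ)`` with multiplicative noise
  ``δ ~ N(0, cv²)`` and a fixed ISTD area per sample, optionally perturbing a
  controlled fraction of rows by a factor ``(1 + outlier_offset)`` and
  recording exactly which rows were perturbed.

Outliers are injected into at most one dilution row per molecule; with seven
levels this makes an offset of 0.8 detectable by the ±0.5·ᾱ single-pass
filter with no false positives or negatives at zero signal noise.

The default concentration ladder is a factor-2 serial dilution over seven
levels from 0.1 mg/kg down, matching the typical 0.001–0.1 mg/kg spiking
range of forensic decision-point experiments; the smallest log-spacing
between levels is then exactly ln 2, the accuracy threshold used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigurationError, SmilesParseError
from .featurize import smiles_to_graph
from .preprocessing import MEASUREMENT_COLUMNS

DEFAULT_CONCENTRATION_LEVELS = tuple(0.1 / 2**k for k in range(7))

BETA_HEAVY_COEF = 0.4
BETA_AROMATIC_COEF = -0.1
BETA_NITROGEN_COEF = 0.8


@dataclass
class MoleculeRecord:
    molecule_id: str
    smiles: str
    target: float | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated spiking experiment."""

    n_molecules: int = 200
    concentration_levels: tuple[float, ...] = DEFAULT_CONCENTRATION_LEVELS
    signal_noise_cv: float = 0.1
    beta_noise_sd: float = 0.1
    outlier_fraction: float = 0.0
    outlier_offset: float = 0.8
    istd_area_mean: float = 1e5
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")
        levels = tuple(float(c) for c in self.concentration_levels)
        if len(levels) == 0:
            raise ConfigurationError("concentration_levels must be non-empty")
        if any(c <= 0 for c in levels):
            raise ConfigurationError("concentration levels must be strictly positive")
        if len(set(levels)) != len(levels):
            raise ConfigurationError("concentration levels must be distinct")
        if self.signal_noise_cv < 0 or self.beta_noise_sd < 0:
            raise ConfigurationError("noise magnitudes must be non-negative")
        if not (0 <= self.outlier_fraction < 1):
            raise ConfigurationError("outlier_fraction must be in [0, 1)")
        if self.outlier_offset <= 0.5:
            raise ConfigurationError(
                "outlier_offset must exceed 0.5 so injected outliers violate the filter"
            )
        object.__setattr__(self, "concentration_levels", levels)


# ---------------------------------------------------------------------------
# molecule grammar
# ---------------------------------------------------------------------------

_TERMINAL_GROUPS = ["", "O", "N", "F", "Cl", "Br"]
_AROMATIC_SUBSTITUENTS = ["C", "CC", "CCC", "O", "N", "F", "Cl", "Br", "CO", "CN", "CCO"]


def _candidate_pool(chain_max: int) -> list[str]:
    """Deterministically ordered, deduplicated pool of valid SMILES."""
    raw: list[str] = []
    for k in range(1, chain_max + 1):
        for g in _TERMINAL_GROUPS:
            raw.append("C" * k + g)
    for k in range(0, max(chain_max - 3, 4)):
        for g in _TERMINAL_GROUPS:
            raw.append("CC(C)" + "C" * k + g)
    raw.append("c1ccccc1")
    for s in _AROMATIC_SUBSTITUENTS:
        raw.append(s + "c1ccccc1")
    for s1 in _AROMATIC_SUBSTITUENTS:
        for s2 in _AROMATIC_SUBSTITUENTS:
            raw.append(s1 + "c1ccc(" + s2 + ")cc1")
    pool: list[str] = []
    seen_canonical: set[str] = set()
    for smi in raw:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen_canonical:
            continue
        seen_canonical.add(canon)
        pool.append(smi)
    return pool


def generate_molecules(n: int, seed: int) -> list[MoleculeRecord]:
    """Draw ``n`` distinct valid SMILES from the grammar, deterministically."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    chain_max = 12
    pool = _candidate_pool(chain_max)
    while len(pool) < n:
        chain_max += 4
        pool = _candidate_pool(chain_max)
    rng = np.random.default_rng(seed)
    picks = rng.permutation(len(pool))[:n]
    width = max(4, len(str(n)))
    return [
        MoleculeRecord(molecule_id=f"M{idx:0{width}d}", smiles=pool[p])
        for idx, p in enumerate(picks)
    ]


def beta_structural(smiles: str) -> float:
    """Deterministic part of the synthetic β rule, from the molecular graph."""
    graph = smiles_to_graph(smiles)
    mol = graph.mol
    n_heavy = mol.GetNumHeavyAtoms()
    n_aromatic = sum(a.GetIsAromatic() for a in mol.GetAtoms())
    has_n = any(a.GetAtomicNum() == 7 for a in mol.GetAtoms())
    return BETA_HEAVY_COEF * n_heavy + BETA_AROMATIC_COEF * n_aromatic + BETA_NITROGEN_COEF * has_n


def assign_beta(
    molecules: list[MoleculeRecord], noise_sd: float, seed: int
) -> list[MoleculeRecord]:
    """Attach β_true = structural rule + N(0, noise_sd²) noise to each record."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in molecules:
        try:
            base = beta_structural(rec.smiles)
        except SmilesParseError as exc:
            raise SmilesParseError(rec.smiles, f"molecule {rec.molecule_id}") from exc
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        out.append(MoleculeRecord(rec.molecule_id, rec.smiles, float(base + eps)))
    return out


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Measurement table plus the ground truth needed for recovery tests."""

    measurements: pd.DataFrame  # row_id, smiles + MEASUREMENT_COLUMNS
    molecules: list[MoleculeRecord]  # with β_true targets
    outlier_row_ids: list[str] = field(default_factory=list)

    def beta_true_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"molecule_id": m.molecule_id, "beta_true": m.target} for m in self.molecules]
        )


def generate_measurements(
    molecules_with_beta: list[MoleculeRecord], spec: SyntheticSpec
) -> SyntheticDataset:
    """Dilution-series areas from β_true, with noise and injected outliers."""
    if any(m.target is None for m in molecules_with_beta):
        raise ConfigurationError("β targets must be assigned before generating measurements")
    levels = spec.concentration_levels
    rng = np.random.default_rng(spec.seed)

    istd_by_sample = {
        f"S{i:02d}": float(spec.istd_area_mean * np.exp(rng.normal(0.0, 0.05)))
        for i in range(len(levels))
    }

    rows = []
    for m in molecules_with_beta:
        for li, c in enumerate(levels):
            sample_id = f"S{li:02d}"
            istd = istd_by_sample[sample_id]
            delta = rng.normal(0.0, spec.signal_noise_cv) if spec.signal_noise_cv > 0 else 0.0
            factor = max(1.0 + delta, 1e-6)
            area = float(np.exp(m.target) * c * istd * factor)
            rows.append(
                {
                    "row_id": f"R{len(rows):06d}",
                    "sample_id": sample_id,
                    "molecule_id": m.molecule_id,
                    "smiles": m.smiles,
                    "concentration_mg_per_kg": c,
                    "area": area,
                    "istd_area": istd,
                }
            )
    df = pd.DataFrame(rows, columns=["row_id", "smiles"] + MEASUREMENT_COLUMNS)

    outlier_row_ids: list[str] = []
    n_outliers = int(round(spec.outlier_fraction * len(df)))
    if n_outliers > 0:
        if n_outliers > len(molecules_with_beta):
            raise ConfigurationError(
                f"outlier_fraction {spec.outlier_fraction} requires {n_outliers} outliers but "
                f"at most one per molecule is injected ({len(molecules_with_beta)} molecules); "
                "lower the fraction or add molecules"
            )
        mol_idx = rng.choice(len(molecules_with_beta), size=n_outliers, replace=False)
        level_idx = rng.integers(0, len(levels), size=n_outliers)
        for mi, li in zip(mol_idx, level_idx):
            row = int(mi) * len(levels) + int(li)
            df.loc[row, "area"] *= 1.0 + spec.outlier_offset
            outlier_row_ids.append(df.loc[row, "row_id"])
        outlier_row_ids.sort()

    return SyntheticDataset(df, list(molecules_with_beta), outlier_row_ids)


def simulate_study(spec: SyntheticSpec) -> SyntheticDataset:
    """Molecules + targets + measurement table in one call, fully seeded."""
    mols = generate_molecules(spec.n_molecules, spec.seed)
    mols = assign_beta(mols, spec.beta_noise_sd, spec.seed + 1)
    return generate_measurements(mols, spec)
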