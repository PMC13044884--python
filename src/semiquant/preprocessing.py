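"""Signal preprocessing: spiked-sample measurements -> one β per molecule.

For every measurement of molecule *m* spiked at concentration *c_m* (mg/kg),
the analyte peak area *s_m* is first corrected by the internal-standard area,
``s̄ = s / s_ISTD``, then converted to the signal-to-concentration ratio
``α = s̄ / c``. Per molecule, the α values are averaged, values deviating
from that mean by more than ±0.5·ᾱ (relative threshold, single pass) are
removed as outliers of the linear range, the mean is recomputed over the
kept values, and ``β = ln(ᾱ)`` is the regression target.

The filter is single-pass: deviations are judged against the mean computed
over *all* values (outliers included), and the mean is recomputed exactly
once after removal. Both the pre- and post-removal means are retained so the
choice is auditable. Rows excluded by an explicit user-supplied exclusion
list (sample ids or molecule ids) and rows that produce non-positive α never
enter the averaging; they are reported in a rejects list with reason codes,
never silently dropped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_REL_THRESHOLD = 0.5


@dataclass(frozen=True)
class Measurement:
    """One spiked-blood LC-HRMS measurement row."""

    sample_id: str
    molecule_id: str
    concentration: float  # mg/kg
    area: float  # analyte peak area (counts)
    istd_area: float  # internal-standard peak area (counts)

    def __post_init__(self):
        if self.concentration <= 0:
            raise InvalidMeasurementError(self.sample_id, f"concentration {self.concentration} <= 0")
        if self.istd_area <= 0:
            raise InvalidMeasurementError(self.sample_id, f"ISTD area {self.istd_area} <= 0")
        if self.area < 0:
            raise InvalidMeasurementError(self.sample_id, f"negative area {self.area}")


@dataclass
class AlphaRecord:
    """Per-molecule signal-to-concentration ratios and their mean."""

    molecule_id: str
    per_measurement_alpha: list[float]
    mean_alpha: float
    n_kept: int
    n_flagged: int = 0
    mean_alpha_prefilter: float | None = None
    flagged_alpha: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class BetaRecord:
    molecule_id: str
    beta: float


@dataclass
class Reject:
    """A measurement row or molecule dropped from the analysis, with reason."""

    molecule_id: str
    sample_id: str | None
    reason: str


def istd_correct(area: float, istd_area: float, sample_id: str = "?") -> float:
    """ISTD-corrected area s̄ = s / s_ISTD."""
    if istd_area <= 0:
        raise InvalidMeasurementError(sample_id, f"ISTD area {istd_area} <= 0")
    if area < 0:
        raise InvalidMeasurementError(sample_id, f"negative area {area}")
    return area / istd_area


def compute_alpha(
    measurements: list[Measurement],
    exclusions: set[str] | list[str] | tuple = (),
) -> tuple[list[AlphaRecord], list[Reject]]:
    """Per-measurement α = s̄ / c, grouped and averaged per molecule.

    ``exclusions`` may contain sample ids and/or molecule ids; matching rows
    are dropped and logged. Rows with zero area give α = 0, which violates
    the positivity invariant and goes to the rejects list, as does any
    molecule left with no usable measurement.
    """
    excl = set(exclusions)
    rejects: list[Reject] = []
    per_mol: dict[str, list[tuple[str, float]]] = {}
    for m in measurements:
        if m.molecule_id in excl:
            rejects.append(Reject(m.molecule_id, m.sample_id, "excluded_molecule"))
            continue
        if m.sample_id in excl:
            rejects.append(Reject(m.molecule_id, m.sample_id, "excluded_sample"))
            continue
        alpha = istd_correct(m.area, m.istd_area, m.sample_id) / m.concentration
        if alpha <= 0:
            rejects.append(Reject(m.molecule_id, m.sample_id, "nonpositive_alpha"))
            continue
        per_mol.setdefault(m.molecule_id, []).append((m.sample_id, alpha))

    seen_molecules = {m.molecule_id for m in measurements}
    for mol_id in sorted(seen_molecules - set(per_mol) - excl):
        rejects.append(Reject(mol_id, None, "no_usable_measurements"))

    records = []
    for mol_id in sorted(per_mol):
        pairs = sorted(per_mol[mol_id])  # deterministic under row permutation
        alphas = [a for _, a in pairs]
        records.append(
            AlphaRecord(
                molecule_id=mol_id,
                per_measurement_alpha=alphas,
                mean_alpha=float(np.mean(alphas)),
                n_kept=len(alphas),
            )
        )
    return records, rejects


def flag_outliers(record: AlphaRecord, rel_threshold: float = DEFAULT_REL_THRESHOLD) -> AlphaRecord:
    """Single-pass relative outlier filter at ±rel_threshold·ᾱ.

    The mean ᾱ is computed over all values, every value with
    ``|α − ᾱ| > rel_threshold·ᾱ`` (strict) is flagged and removed, and the
    mean is recomputed once over the kept values. If the filter would flag
    everything, all values are kept and a warning is emitted.
    """
    alphas = np.asarray(record.per_measurement_alpha, dtype=float)
    if alphas.size == 0:
        raise ValueError(f"molecule {record.molecule_id!r}: no alpha values to filter")
    mean_all = float(alphas.mean())
    keep = np.abs(alphas - mean_all) <= rel_threshold * mean_all
    if not keep.any():
        warnings.warn(
            f"molecule {record.molecule_id!r}: outlier filter would remove every "
            "measurement; keeping all values",
            stacklevel=2,
        )
        keep[:] = True
    kept = alphas[keep]
    return AlphaRecord(
        molecule_id=record.molecule_id,
        per_measurement_alpha=[float(a) for a in kept],
        mean_alpha=float(kept.mean()),
        n_kept=int(keep.sum()),
        n_flagged=int((~keep).sum()),
        mean_alpha_prefilter=mean_all,
        flagged_alpha=[float(a) for a in alphas[~keep]],
    )


def compute_beta(alpha_records: list[AlphaRecord]) -> list[BetaRecord]:
    """β = ln(ᾱ) per molecule."""
    out = []
    for rec in alpha_records:
        if rec.mean_alpha <= 0:
            raise ValueError(f"molecule {rec.molecule_id!r}: mean alpha {rec.mean_alpha} <= 0")
        out.append(BetaRecord(rec.molecule_id, math.log(rec.mean_alpha)))
    return out


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = [
    "sample_id",
    "molecule_id",
    "concentration_mg_per_kg",
    "area",
    "istd_area",
]


@dataclass
class PreprocessResult:
    alpha_records: list[AlphaRecord]
    beta_records: list[BetaRecord]
    rejects: list[Reject]

    def beta_frame(self) -> pd.DataFrame:
        rows = []
        beta_by_id = {b.molecule_id: b.beta for b in self.beta_records}
        for rec in self.alpha_records:
            rows.append(
                {
                    "molecule_id": rec.molecule_id,
                    "mean_alpha": rec.mean_alpha,
                    "beta": beta_by_id[rec.molecule_id],
                    "n_kept": rec.n_kept,
                    "n_flagged": rec.n_flagged,
                }
            )
        return pd.DataFrame(rows, columns=["molecule_id", "mean_alpha", "beta", "n_kept", "n_flagged"])

    def rejects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"molecule_id": r.molecule_id, "sample_id": r.sample_id, "reason": r.reason} for r in self.rejects],
            columns=["molecule_id", "sample_id", "reason"],
        )


def measurements_from_frame(df: pd.DataFrame) -> list[Measurement]:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurements table is missing columns {missing}")
    return [
        Measurement(
            sample_id=str(r.sample_id),
            molecule_id=str(r.molecule_id),
            concentration=float(r.concentration_mg_per_kg),
            area=float(r.area),
            istd_area=float(r.istd_area),
        )
        for r in df.itertuples(index=False)
    ]


def preprocess_measurements(
    df: pd.DataFrame,
    exclusions: set[str] | list[str] | tuple = (),
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> PreprocessResult:
    """Full preprocessing: measurements table -> β per molecule + audit trail."""
    measurements = measurements_from_frame(df)
    alpha_records, rejects = compute_alpha(measurements, exclusions)
    filtered = [flag_outliers(rec, rel_threshold) for rec in alpha_records]
    n_removed = sum(r.n_flagged for r in filtered)
    if n_removed:
        logger.info("outlier filter removed %d of %d measurements", n_removed, len(measurements))
    return PreprocessResult(filtered, compute_beta(filtered), rejects)
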