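"""Exception hierarchy shared across the package."""


class SemiquantError(Exception):
    """Base class for all package errors."""


class SmilesParseError(SemiquantError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class FeaturizationError(SemiquantError):
    """Featurization failed (embedding failure, missing element data, ...)."""


class InvalidMeasurementError(SemiquantError):
    """A measurement row violates its invariants (e.g. non-positive ISTD area)."""

    def __init__(self, sample_id: str, detail: str):
        self.sample_id = sample_id
        super().__init__(f"invalid measurement in sample {sample_id!r}: {detail}")


class ConfigurationError(SemiquantError):
    """A configuration object or file is invalid."""


class SchemaError(SemiquantError):
    """A delimited input file does not match the documented schema."""


class TrainingError(SemiquantError):
    """Model training failed (divergence, non-finite loss)."""

    def __init__(self, detail: str, epoch: int | None = None):
        self.epoch = epoch
        if epoch is not None:
            detail = f"{detail} (epoch {epoch})"
        super().__init__(detail)
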