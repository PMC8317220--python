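"""Exception hierarchy shared across the pipeline."""


class MetabotypeError(Exception):
    """Base class for all package errors."""


class SchemaError(MetabotypeError):
    """A required column or field is missing from an input table."""


class CohortValidationError(MetabotypeError):
    """One or more records violate unit-range or type rules.

    Carries per-row diagnostics in ``messages``.
    """

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("cohort validation failed:\n" + "\n".join(self.messages))


class IntegrityError(MetabotypeError):
    """Structural violation, e.g. duplicate patient_id within a cohort."""


class IncompleteCurveError(MetabotypeError):
    """An OGTT curve is missing grid points; route through imputation."""


class ModelFormatError(MetabotypeError):
    """A serialized model file is unreadable or version-incompatible."""


class SizeError(MetabotypeError):
    """Too few observations for the requested operation."""


class StratumError(MetabotypeError):
    """A required sex stratum is absent or too small."""


class DegenerateVariableError(MetabotypeError):
    """A variable has zero spread and cannot be z-normalized."""


class LabelingError(MetabotypeError):
    """Subtype labeling rule hit a tie in a deciding variable."""


class MatchingError(MetabotypeError):
    """Two partitions cannot be matched (different cluster counts)."""

    def __init__(self, message, contingency=None):
        super().__init__(message)
        self.contingency = contingency


class NoImputationModelError(MetabotypeError):
    """No trained model covers a record's availability pattern."""


class PatternError(MetabotypeError):
    """An availability or missingness pattern is invalid."""


class ConfigError(MetabotypeError):
    """A configuration value is out of its admissible range."""


class DegenerateTableError(MetabotypeError):
    """A contingency table has a zero marginal."""


class TransformError(MetabotypeError):
    """A variable transform is undefined for some values (e.g. log of <= 0)."""
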