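"""Exception hierarchy for the metabopls pipeline."""


class MetaboPLSError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(MetaboPLSError):
    """A table is missing required columns or features."""


class TableValidationError(MetaboPLSError):
    """A table violates a documented invariant (range, duplicates, NaN)."""


class TableParseError(MetaboPLSError):
    """A cell could not be parsed; message carries row/column coordinates."""


class ConfigError(MetaboPLSError):
    """A run configuration or synthetic spec violates its invariants."""


class DegenerateModelError(MetaboPLSError):
    """A model cannot be fitted or evaluated (zero variance, rank exhausted)."""


class FoldDegeneracyError(DegenerateModelError):
    """A cross-validation training split has zero response variance."""


class SelectionError(MetaboPLSError):
    """VIP threshold selection found no fittable candidate model."""


class StabilityError(MetaboPLSError):
    """Monte Carlo stability analysis could not produce valid subsamples."""


class ReportError(MetaboPLSError):
    """Assembled results are incomplete for report emission."""
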