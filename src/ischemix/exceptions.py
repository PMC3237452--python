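"""Exception hierarchy for ischemix."""


class IschemixError(Exception):
    """Base class for all ischemix errors."""


class ConfigError(IschemixError, ValueError):
    """Invalid or dimension-inconsistent generator/study configuration."""


class ValidationError(IschemixError, ValueError):
    """Malformed input data (CSV layout, duplicate keys, ragged batches...)."""


class PreprocessError(IschemixError, ValueError):
    """Preprocessing cannot proceed (e.g. a reference column has no valid data)."""


class ModelError(IschemixError, ValueError):
    """Model fitting or application failed."""


class DegenerateDataError(ModelError):
    """Training data carry no usable variance (e.g. identical batches)."""


class ConvergenceError(ModelError):
    """Iterative fit failed to converge."""

    def __init__(self, message: str, component: int | None = None):
        super().__init__(message)
        self.component = component
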