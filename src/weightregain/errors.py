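"""Exception hierarchy shared across the package."""


class WeightRegainError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WeightRegainError):
    """A table does not conform to the documented column schema."""


class IntegrityError(WeightRegainError):
    """Data violate an invariant (duplicate keys, impossible counts...)."""


class EstimationError(WeightRegainError):
    """A model parameter is inestimable from the data supplied."""


class StabilityError(WeightRegainError):
    """A difference-equation step produced an invalid (negative) state.

    Raised when annual rates are too large for the explicit annual step;
    the message carries the offending stratum/year for diagnosis.
    """
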