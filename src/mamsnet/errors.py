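"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A design, scenario or chart parameter is outside its valid range."""


class CalibrationError(RuntimeError):
    """The boundary/sample-size search failed to bracket a solution."""


class ConfigurationError(ValueError):
    """A required piece of configuration (e.g. a stage boundary) is missing."""


class DataExhaustedError(RuntimeError):
    """An outcome stream or randomization table ran out of rows."""


class CapacityError(DataExhaustedError):
    """A randomization stratum has no unconsumed rows left."""


class DataIntegrityError(ValueError):
    """Input tables violate referential or milestone consistency."""
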