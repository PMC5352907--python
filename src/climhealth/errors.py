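"""Exception hierarchy shared across the pipeline stages."""


class ClimHealthError(Exception):
    """Base class for all package errors."""


class InputError(ClimHealthError):
    """Raised when supplied data violates a documented contract
    (unsorted dates, unknown indicator ids, non-finite values, ...)."""


class ConfigurationError(ClimHealthError):
    """Raised when a configuration object is internally inconsistent
    (embedded run outside the simulated range, standard without a value, ...)."""
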