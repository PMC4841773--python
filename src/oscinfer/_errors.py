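"""Shared exception types."""


class ConfigurationError(ValueError):
    """A stimulus, grid, effect or analysis configuration is incoherent."""


class DegeneratePosteriorError(RuntimeError):
    """Every parameter combination assigns zero mass to the observations."""


class UndefinedEvidenceError(ValueError):
    """Both change and no-change likelihoods are zero; Bayes' rule undefined."""


class FormatError(IOError):
    """A recording container does not match the documented schema/version."""
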