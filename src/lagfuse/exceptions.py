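"""Exception hierarchy."""


class LagfuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LagfuseError, ValueError):
    """An invalid configuration object or parameter."""


class CurationError(LagfuseError, ValueError):
    """A pre-modelling curation step received data it cannot handle."""


class ContractViolation(LagfuseError, ValueError):
    """An interface precondition was violated (shape, alignment, anchor)."""


class OrchestrationError(LagfuseError, RuntimeError):
    """A pipeline stage is missing an input it depends on."""


class TrainingDivergence(LagfuseError, RuntimeError):
    """Training produced a non-finite loss."""
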