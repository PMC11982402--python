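"""Exception types shared across the package."""


class FusesegError(Exception):
    """Base class for package errors."""


class ValidationError(FusesegError):
    """Input data violates a documented precondition."""


class RegistrationError(ValidationError):
    """PET/CT/mask volumes are not on a common grid."""


class DegenerateInputError(ValidationError):
    """An operation is undefined for this input (e.g. constant PET volume)."""


class ConfigurationError(FusesegError):
    """A model or run configuration is inconsistent."""


class FusionError(FusesegError):
    """Feature maps entering the fusion block are incompatible."""


class GenerationError(FusesegError):
    """Phantom geometry could not be realized."""
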