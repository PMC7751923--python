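"""Exception hierarchy shared across the package."""


class PBRError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PBRError, ValueError):
    """A physical quantity is outside its valid domain."""


class ConfigError(PBRError, ValueError):
    """A configuration file or table schema is malformed."""


class SolverError(PBRError, RuntimeError):
    """A numerical solve failed to converge or produced an invalid solution."""


class IdentifiabilityError(PBRError, ValueError):
    """The observation design cannot determine the requested parameters."""
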