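"""Exception types shared across the package."""


class ActisyncError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ActisyncError, ValueError):
    """A device export or journal file violates its dialect contract."""


class ConfigurationError(ActisyncError, ValueError):
    """A configuration object violates one of its invariants."""


class RegistrationError(ActisyncError, ValueError):
    """The two device streams cannot be placed on a common minute grid."""


class DomainError(ActisyncError, ValueError):
    """An operation received a value outside its mathematical domain."""
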