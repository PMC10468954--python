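"""Exception hierarchy."""


class FluxGeomError(Exception):
    """Base class for all package-specific errors."""


class NetworkParseError(FluxGeomError, ValueError):
    """Malformed network file or schema violation."""


class CapabilityError(FluxGeomError, RuntimeError):
    """A requested optional capability (e.g. SBML) is unavailable."""


class DomainError(FluxGeomError, ValueError):
    """A flux vector violates a required membership condition."""


class StateError(FluxGeomError, RuntimeError):
    """An operation requires a canonical cone description."""


class ResourceError(FluxGeomError, RuntimeError):
    """A configured size guard was exceeded."""


class VerificationError(FluxGeomError, AssertionError):
    """A mathematical invariant that must hold was violated."""
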