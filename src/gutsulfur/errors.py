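"""Exception hierarchy shared across the package."""


class GutSulfurError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GutSulfurError):
    """A file does not conform to its declared dialect."""


class ValidationError(GutSulfurError):
    """Input content violates a domain invariant."""


class ResolutionError(GutSulfurError, KeyError):
    """A gene symbol or profile id does not resolve in the active catalog."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep messages readable
        return Exception.__str__(self)
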