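"""Exception hierarchy.

All expected failure modes raise a subclass of :class:`StrongPathsError` so
that the CLI can map them to exit code 1; anything else is an internal error
(exit code 2).
"""


class StrongPathsError(Exception):
    """Base class for all anticipated errors."""


class FormatError(StrongPathsError):
    """A file does not conform to the expected dialect (names the line)."""


class ValidationError(StrongPathsError):
    """Parsed content violates a domain constraint (e.g. score out of (0,1])."""


class InputError(StrongPathsError):
    """Invalid arguments to an operation (empty sets, negative epsilon, ...)."""


class ResolutionError(StrongPathsError):
    """An identifier could not be resolved (or resolved ambiguously where a
    unique node is required)."""
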