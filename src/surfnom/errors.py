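"""Exception hierarchy.

Every hard error raised by the library derives from :class:`SurfnomError`
so the command-line layer can map any domain failure to a nonzero exit
code with a single-line diagnostic.
"""


class SurfnomError(Exception):
    """Base class for all domain errors."""


class ValidationError(SurfnomError):
    """An input matrix, table, or configuration violates an invariant."""


class MissingLengthError(ValidationError):
    """A feature being quantified has no annotated length."""


class MissingGroupError(ValidationError):
    """A group label required by an operation is absent from the design."""


class MissingMappingError(ValidationError):
    """A transcript has no parent-gene assignment."""
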