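"""Exception hierarchy.

Everything raised for a *user-input* problem derives from :class:`ICTNetError`
so the CLI can map it to a clean diagnostic and a distinct exit code.
"""


class ICTNetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ICTNetError):
    """A tabular input file violates the expected format (names the line)."""


class ReferentialIntegrityError(ICTNetError):
    """An edge references a node that does not exist in the network."""


class DuplicateEdgeError(ICTNetError):
    """Two edges share the same (source, target, edge_type) triple."""


class DomainError(ICTNetError, ValueError):
    """A parameter or value lies outside its documented domain."""


class LookupMissError(ICTNetError, KeyError):
    """A requested node id is not present in the network."""


class UnmappedSNPError(ICTNetError):
    """No gene annotation exists on the chromosome of an association record."""
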