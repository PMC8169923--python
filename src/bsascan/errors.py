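"""Exception hierarchy for the toolkit.

All errors derive from :class:`BsascanError` so callers can catch the
toolkit's failures with a single except clause; the subclasses separate
user-configuration mistakes from malformed inputs and internal bugs.
"""


class BsascanError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(BsascanError, ValueError):
    """A parameter or option supplied by the user is invalid
    (unknown sample ID, unrecognized design/role pair, impossible
    heritability setting, ...)."""


class InputError(BsascanError, ValueError):
    """An input file violates its contract (unsorted VCF, site beyond
    the declared chromosome length, ...)."""


class DomainError(BsascanError, ValueError):
    """A numeric argument lies outside the mathematical domain of an
    operation (e.g. an allele frequency outside [0, 1])."""


class InternalConsistencyError(BsascanError, RuntimeError):
    """The toolkit produced or was handed structures that break its own
    invariants (e.g. overlapping regions on one chromosome)."""
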