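"""Exception hierarchy shared across the package."""


class IndelMarkError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IndelMarkError):
    """An input file violates its format contract (message names the location)."""


class ReferenceMismatchError(IndelMarkError):
    """A variant's REF allele disagrees with the reference sequence at its site."""


class DesignError(IndelMarkError):
    """A primer-design or marker-application precondition was violated."""
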