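"""Exception hierarchy.

Everything raised intentionally by the package derives from
:class:`CladetraceError`, so callers (and the CLI) can distinguish domain
errors from genuine bugs.
"""


class CladetraceError(Exception):
    """Base class for all errors raised by cladetrace."""


class AlignmentError(CladetraceError):
    """Malformed alignment (unequal lengths, duplicate names, bad alphabet)."""


class SaturationError(CladetraceError):
    """Observed differences outside a distance correction's domain."""


class ZeroComparableSitesError(CladetraceError):
    """A sequence pair shares no site that is unambiguous in both."""


class ScenarioError(CladetraceError):
    """Invalid scenario specification or introgression event."""


class TreeError(CladetraceError):
    """Invalid tree input (missing leaf, undated, label mismatch, ...)."""
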