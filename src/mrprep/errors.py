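"""Exception hierarchy for mrprep.

All errors derive from :class:`MrprepError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the matching builtin (``ValueError``/``OSError``) so generic handling
keeps working.
"""


class MrprepError(Exception):
    """Base class for all mrprep errors."""


class FormatError(MrprepError, ValueError):
    """Input file violates the expected format (no ATOM records, bad header, ...)."""


class ConsistencyError(MrprepError, ValueError):
    """Two objects that must agree do not (rosters, matrix shapes, parameters)."""


class PreconditionError(MrprepError, ValueError):
    """An operation's stated precondition is not met."""


class RangeError(MrprepError, ValueError):
    """A value falls outside the representable or allowed range."""
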