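"""Exception hierarchy shared across the package.

Everything derives from :class:`OmicascadeError` so callers can catch the
package's failures with a single except clause; parse/validation errors carry
enough coordinates to locate the offending cell or sample.
"""

from __future__ import annotations


class OmicascadeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(OmicascadeError, ValueError):
    """A configuration object violates one of its invariants.

    The message names the violated invariant.
    """


class ValidationError(OmicascadeError, ValueError):
    """Input data violate a documented precondition."""


class ParseError(OmicascadeError, ValueError):
    """A file could not be parsed; the message cites row/column coordinates."""


class AlignmentError(OmicascadeError, ValueError):
    """Sample rosters of two matrices disagree.

    The message lists the symmetric difference of the rosters.
    """


class InsufficientDataError(OmicascadeError, ValueError):
    """Fewer than the minimum number of complete cases for a test (n < 3)."""


class DomainError(OmicascadeError, ValueError):
    """A value is outside the mathematical domain of a transform."""
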