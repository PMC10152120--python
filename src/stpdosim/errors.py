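"""Exception hierarchy for stpdosim.

All package-raised errors derive from :class:`StpDosimError` so callers can
catch the package's failures with a single except clause while still
distinguishing validation problems (malformed inputs) from domain problems
(inputs that are well-formed but mathematically inadmissible, e.g. a
non-decaying curve handed to a time-integral).
"""


class StpDosimError(Exception):
    """Base class for all stpdosim errors."""


class ValidationError(StpDosimError, ValueError):
    """Input violates a structural precondition (shape, sign, ordering)."""


class DomainError(StpDosimError, ValueError):
    """Input is structurally valid but outside the mathematical domain."""


class InsufficientDataError(StpDosimError, ValueError):
    """Too few observations for the requested operation."""
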