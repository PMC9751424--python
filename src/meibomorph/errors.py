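"""Exception hierarchy.

The CLI maps these onto distinct exit codes so shell pipelines can tell
validation problems (bad masks, bad configs) from I/O failures and from
statistical degeneracy (too few pairs, constant data).
"""


class MeibomorphError(Exception):
    """Base class for all package errors."""


class ValidationError(MeibomorphError):
    """Input violates a documented precondition (shape, range, format)."""


class MaskConsistencyError(ValidationError):
    """Gland / tarsus masks are mutually inconsistent (e.g. gland outside tarsus)."""


class DegenerateStatisticsError(MeibomorphError):
    """A statistical routine was handed data it cannot test (n too small, constant)."""
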