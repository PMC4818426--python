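"""Exception hierarchy for the insertion-site pipeline.

Every rejection category a junction record can fall into has its own
exception so that the batch driver can account for each input record
exactly once (called event or one named reject reason).
"""


class Tol2SitesError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(Tol2SitesError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class EmptyInputError(Tol2SitesError, ValueError):
    """An operation that needs at least one observation received none."""


class UnparseableJunctionError(Tol2SitesError):
    """Neither transposon terminal could be located in a junction record."""


class ChimericJunctionError(Tol2SitesError):
    """Both transposon terminals occur in a single junction record."""


class UnmappedFlankError(Tol2SitesError):
    """A target flank has no exact anchor hit on the circular plasmid."""


class DiscordantJunctionPairError(Tol2SitesError):
    """Left/right flank mappings are inconsistent with any duplication
    length in the allowed range (wrong strands or too far apart)."""


class AmbiguousAnnotationError(Tol2SitesError):
    """Plasmid features overlap, so length-proportional multinomial
    probabilities are ill-defined."""


class UndefinedRatioError(Tol2SitesError, ZeroDivisionError):
    """Integration ratio requested with zero recovered target plasmids."""


class UnsupportedSizeError(Tol2SitesError, ValueError):
    """Exact enumeration requested for an instance too large to enumerate."""
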