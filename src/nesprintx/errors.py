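"""Exception hierarchy.

All package errors derive from :class:`NesprintxError` so callers can catch a
single base class at pipeline boundaries.
"""


class NesprintxError(Exception):
    """Base class for all nesprintx errors."""


class NotFoundError(NesprintxError, KeyError):
    """A requested gene, exon, intron or anchor does not exist."""


class BoundsError(NesprintxError):
    """A coordinate falls outside its contig or locus."""


class ModelError(NesprintxError):
    """A gene model violates a structural invariant (e.g. overlapping exons)."""


class ParameterError(NesprintxError, ValueError):
    """An operation parameter is outside its documented range."""


class OrientationError(NesprintxError):
    """Primer or interval orientation contradicts transcription order."""


class NoOrfError(NesprintxError):
    """No usable start codon was found in a transcript."""


class PatternError(NesprintxError):
    """A cassette inclusion pattern references a constitutive exon."""


class MassError(NesprintxError, ValueError):
    """A peptide contains residues without a defined average mass."""


class InputError(NesprintxError, ValueError):
    """Malformed input value (sequence, offset, table)."""


class ConfigError(NesprintxError):
    """A simulation or pipeline configuration is invalid or infeasible."""
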