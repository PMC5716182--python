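"""Exception hierarchy shared by all trapforge modules."""


class TrapforgeError(Exception):
    """Base class for all package errors."""


class InvalidMotifError(TrapforgeError):
    """Motif contains a non-IUPAC character or is too short."""


class DegenerateCutError(TrapforgeError):
    """Both cut offsets coincide; nothing to excise."""


class EmptyTranscriptError(TrapforgeError):
    """Gene model without exons cannot be spliced."""


class ParseError(TrapforgeError):
    """Malformed input record; message names the offending record/line."""


class MissingSiteError(TrapforgeError):
    """A required recombination site subtype is absent."""


class AmbiguousSiteError(TrapforgeError):
    """More sites of one subtype than the operation can resolve."""


class OrientationError(TrapforgeError):
    """Recombination sites are not co-oriented (direct repeats required)."""


class NoSiteError(TrapforgeError):
    """Linearization motif absent from the plasmid."""


class MultipleSiteError(TrapforgeError):
    """More than one linearization motif; the plasmid cannot be opened intact."""


class NoIntegrationError(TrapforgeError):
    """Vector homology arms do not match the target allele."""


class MustLinearizeError(TrapforgeError):
    """Circular vectors do not integrate; linearize first."""


class NoFrameError(TrapforgeError):
    """No coding exon inside the homology region; reading frame undefined."""


class UnsuitableVectorError(TrapforgeError):
    """Extra linearization-motif occurrences inside the homology region."""


class AssemblyLogicError(TrapforgeError):
    """Post-assembly census failed (e.g. rpsL still present after Cre)."""


class CoordinateError(TrapforgeError):
    """Interval outside the bounds of its sequence."""


class ConstructionError(TrapforgeError):
    """Requested allele/cell-line structure is not reachable."""


class GenerationError(TrapforgeError):
    """Fixture generator constraints are infeasible."""


class GeometryError(TrapforgeError):
    """Vector arm geometry conflicts with the gene model."""


class ProtocolError(TrapforgeError):
    """Workflow step applied to a cell line that cannot support it."""


class ConfigError(TrapforgeError):
    """Unknown drug, marker or configuration key."""


class DataError(TrapforgeError):
    """Inconsistent tally table (e.g. positives exceed screened)."""


class DesignError(TrapforgeError):
    """No primer placement satisfies the external-primer rule."""
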