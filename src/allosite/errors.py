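"""Exception hierarchy for the allosite pipeline.

Every stage raises a subclass of :class:`AllositeError` so the command-line
driver can tag failures with the stage that produced them.
"""


class AllositeError(Exception):
    """Base class for all pipeline errors."""


class AnnotationError(AllositeError):
    """Receptor annotation is internally inconsistent (overlapping segments,
    anchor outside its segment, generic index out of the 1-99 range)."""


class RangeError(AllositeError):
    """A sequence index falls outside the receptor sequence."""


class ParseError(AllositeError):
    """An input file could not be parsed."""


class ConfigurationError(AllositeError):
    """Run configuration is inconsistent (unknown chain, mixed cutoffs...)."""


class SelectionError(AllositeError):
    """A ligand selection resolved to zero atoms."""


class FormatError(AllositeError):
    """A tabular input is missing mandatory columns."""


class ParameterError(AllositeError):
    """A numeric parameter is outside its valid range."""


class UndefinedDistanceError(AllositeError):
    """A pairwise sequence distance cannot be computed (no comparable columns)."""


class InputError(AllositeError):
    """Generic invalid input to an operation (too few taxa, missing leaf...)."""


class LookupError_(AllositeError):
    """A generic position is mappable in no receptor of the alignment."""


class GenerationError(AllositeError):
    """Synthetic-data generation could not satisfy its geometric constraints."""
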