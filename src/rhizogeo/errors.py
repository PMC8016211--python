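"""Exception hierarchy shared across the package."""


class RhizogeoError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(RhizogeoError):
    """Malformed alignment: unequal row lengths, bad records."""


class DuplicateIdError(AlignmentError):
    """Two records share a strain id."""


class AlphabetError(AlignmentError):
    """Sequence contains a character outside {ACGT, gap, IUPAC codes}."""


class EmptyOverlapError(RhizogeoError):
    """Harmonization left no shared strain ids."""


class InsufficientDataError(RhizogeoError):
    """Operation needs more rows/strains than supplied."""


class UndefinedDistanceError(RhizogeoError):
    """A pair of sequences has no comparable columns (or no co-typed loci)."""


class SaturationError(RhizogeoError):
    """Distance correction undefined: logarithm argument non-positive."""


class ParameterError(RhizogeoError):
    """Invalid numeric parameter (replicates, window width, ...)."""


class RootingError(RhizogeoError):
    """Clade logic requires a rooted tree."""


class SupportMissingError(RhizogeoError):
    """Internal edges lack bootstrap supports."""


class DegenerateTableError(RhizogeoError):
    """Contingency table with no counts."""


class CollinearityError(RhizogeoError):
    """Covariate matrix perfectly collinear with the tested matrix."""


class ConfigError(RhizogeoError):
    """Impossible or inconsistent configuration."""
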