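"""Exception hierarchy for ligdyn."""


class LigdynError(Exception):
    """Base class for all ligdyn errors."""


class ParseError(LigdynError):
    """Malformed input file; message names the offending line where possible."""


class StructureError(LigdynError):
    """Inconsistent molecular structure (e.g. atom count differs between models)."""


class AnnotationError(LigdynError):
    """Chemical-role annotation failed (unknown residues, missing hydrogens)."""


class SelectionError(LigdynError):
    """An atom selection resolved to nothing or used invalid fields."""


class FitError(LigdynError):
    """Rigid-body superposition could not be computed."""


class PruningCollapseError(FitError):
    """Iterative pruning discarded too many atom pairs to continue fitting."""


class InsufficientFramesError(LigdynError):
    """An operation requires more trajectory frames than were provided."""


class SchemaError(LigdynError):
    """A tabular input is missing required columns."""


class ConstructionError(LigdynError):
    """A synthetic fixture could not be built to the requested geometry."""
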