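"""Exception hierarchy for the sgnn package."""


class SgnnError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(SgnnError):
    """Input is not valid FASTA (e.g. no '>' header)."""


class DuplicateIdError(SgnnError):
    """Two records in one dataset share an identifier."""


class InvalidResidueError(SgnnError):
    """A sequence contains a character outside the 20 canonical residues."""


class LabelingError(SgnnError):
    """A record is missing a class label, or a label value is unknown."""


class ParameterError(SgnnError):
    """An operation was called with an invalid parameter."""


class SequenceLengthError(SgnnError):
    """A sequence is shorter than the scoring window requires."""


class ConfigurationError(SgnnError):
    """A configuration object violates its invariants."""


class DegenerateTrainingError(SgnnError):
    """Training data contains only one class."""


class DivergenceError(SgnnError):
    """Training produced a non-finite error value."""


class ModelLoadError(SgnnError):
    """A serialized model bundle is corrupted or has the wrong version."""


class SplitError(SgnnError):
    """A stratified split cannot produce non-empty halves for every class."""


class DegenerateEvaluationError(SgnnError):
    """An evaluation requires both classes but only one is present."""
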