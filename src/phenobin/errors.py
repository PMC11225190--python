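"""Named validation errors raised across the package.

Every input-validation failure maps to a distinct exception type so that
callers (and the CLI) can report precisely which contract was violated.
"""


class PhenobinError(Exception):
    """Base class for all phenobin errors."""


class ValidationError(PhenobinError):
    """Base class for input-validation failures."""


class UnknownCharacterError(ValidationError):
    """A character id in the data has no matching CharacterSpec."""


class StateOutOfRangeError(ValidationError):
    """A coded state is >= the character's declared number of states."""


class DuplicateSpecimenError(ValidationError):
    """Two rows share the same specimen id."""


class DuplicateLabelError(ValidationError):
    """A tree contains duplicate terminal labels."""


class PolytomyError(ValidationError):
    """A tree contains a polytomy and the policy is 'reject'."""


class TreeFormatError(ValidationError):
    """Unreadable newick or too few terminals."""


class RaggedAlignmentError(ValidationError):
    """Sequences within one alignment differ in length."""


class EmptyAlignmentError(ValidationError):
    """An alignment file contains no sequences."""


class LabelMismatchError(ValidationError):
    """Tree terminals and matrix specimens do not correspond."""


class ScenarioError(ValidationError):
    """A grouping scenario violates its invariants."""


class OverlappingCladesError(ValidationError):
    """Two named clades in a clade map share terminals."""


class CodingError(ValidationError):
    """Continuous-to-ordered coding cannot proceed (empty or non-finite)."""


class MissingDataError(ValidationError):
    """An operation received only missing values."""


class DegenerateDistancesError(PhenobinError):
    """All pairwise distances are zero; MRPP's A is undefined."""


class ImputationError(PhenobinError):
    """A missing cell has no same-taxon donor under strict policy."""


class PipelineStageError(PhenobinError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
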