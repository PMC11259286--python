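"""Exception hierarchy.

Two branches matter to callers (and to the CLI exit codes): problems with
the *data* (``ValidationError`` and subclasses) versus problems arising
*during computation* (``ComputationError`` and subclasses).
"""


class ConceptMapError(Exception):
    """Base class for all package errors."""


class ValidationError(ConceptMapError):
    """Input data violates a documented invariant."""


class PartitionError(ValidationError):
    """A sort record is not an exact partition of the statement set."""


class IncompleteSortError(PartitionError):
    """A sorter left statements out of every pile."""


class ReferenceError_(ValidationError):
    """A record refers to a statement_id outside the statement set."""


class DuplicateRatingError(ValidationError):
    """Two ratings for the same (rater, statement) pair."""


class ComputationError(ConceptMapError):
    """A numerical stage failed on otherwise-valid inputs."""


class DegenerateInputError(ComputationError):
    """Input is valid but degenerate for the requested computation."""
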