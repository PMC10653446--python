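"""Exception hierarchy.

Validation errors (bad arguments, malformed configuration) and data errors
(inputs that are structurally fine but scientifically unusable) are kept on
separate branches so the CLI can map them to distinct exit codes.
"""


class RnaSizeBiasError(Exception):
    """Base class for all package errors."""


class ValidationError(RnaSizeBiasError, ValueError):
    """Invalid argument, configuration value, or precondition violation."""


class DataError(RnaSizeBiasError):
    """Structurally valid input that cannot be analysed."""


# -- validation branch ------------------------------------------------------

class InvalidRangeError(ValidationError):
    """A size range with lo > hi."""


class ArityError(ValidationError):
    """Too few operands for a set or group operation."""


class UnitError(ValidationError):
    """An expression matrix carried the wrong unit tag for an operation."""


class DomainError(ValidationError):
    """Numerical argument outside the mathematical domain of a function."""


# -- data branch ------------------------------------------------------------

class EmptyInputError(DataError):
    """An operation received an empty table or matrix."""


class MissingVariantError(DataError):
    """A gene had no variant-rank-1 record under the variant-one rule."""

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id!r} has no variant-rank-1 record")


class BiotypeConflictError(DataError):
    """A gene appeared with more than one biotype."""

    def __init__(self, gene_id: str, biotypes):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id!r} has conflicting biotypes: {sorted(biotypes)}")


class MissingLengthError(DataError):
    """Genes in an expression matrix lack a reference length."""

    def __init__(self, gene_ids):
        self.gene_ids = list(gene_ids)
        head = ", ".join(self.gene_ids[:10])
        more = "" if len(self.gene_ids) <= 10 else f" (+{len(self.gene_ids) - 10} more)"
        super().__init__(f"{len(self.gene_ids)} gene(s) without reference length: {head}{more}")


class DegenerateSampleError(DataError):
    """A sample column with zero total signal."""

    def __init__(self, sample_ids):
        self.sample_ids = list(sample_ids)
        super().__init__(f"sample(s) with zero total counts: {', '.join(self.sample_ids)}")


class NoReferenceGeneError(DataError):
    """No gene has strictly positive counts in every sample."""


class AlignmentError(DataError):
    """Two matrices that must share gene/sample indices do not."""


class InsufficientDataError(DataError):
    """Too few usable points for a fit or statistic."""


class InsufficientReplicationError(DataError):
    """Fewer samples than the statistic requires."""


class UndefinedFractionError(DataError):
    """Recovery fraction over an empty reference set."""


class DimensionError(DataError):
    """Mismatched dimensions between a config and a data object."""


class PipelineHaltError(DataError):
    """The filter cascade removed every gene; downstream steps cannot run."""
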