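"""Exception types shared across the pipeline."""


class IncisMirError(Exception):
    """Base class for all package-specific errors."""


class InvalidAnnotationError(IncisMirError):
    """A miRNA locus annotation violates its contract (bad sequence, alphabet...)."""


class UnassignableLocusError(IncisMirError):
    """One or more loci could not be assigned any methylation probe."""

    def __init__(self, locus_ids):
        self.locus_ids = sorted(locus_ids)
        super().__init__(
            "no methylation probe assignable to loci: " + ", ".join(self.locus_ids)
        )


class MatrixFormatError(IncisMirError):
    """A locus x sample matrix file or object violates the format contract."""


class EmptyMatrixError(IncisMirError):
    """An operation produced or received a matrix with no usable rows/columns."""


class PipelineStageError(IncisMirError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
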