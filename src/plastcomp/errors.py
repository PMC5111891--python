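"""Exception hierarchy for plastcomp."""


class PlastcompError(Exception):
    """Base class for all plastcomp errors."""


class SequenceError(PlastcompError):
    """Invalid sequence input (empty, bad alphabet, all-ambiguous)."""


class NoQuadripartiteStructureError(PlastcompError):
    """No inverted-repeat pair of the required length exists."""


class AmbiguousStructureError(PlastcompError):
    """Two non-equivalent maximal IR pairs tie in length."""


class NonCollinearError(PlastcompError):
    """Anchor chain covers too little of either genome; inputs are not
    collinear (large rearrangement, or missing canonical rotation)."""


class AnnotationError(PlastcompError):
    """Annotation file failed to parse or contains invalid coordinates."""


class SimulationError(PlastcompError):
    """Synthetic-genome construction could not satisfy its constraints."""


class PipelineError(PlastcompError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
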