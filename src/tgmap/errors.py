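"""Exception hierarchy for the tgmap pipeline."""


class TgmapError(Exception):
    """Base class for all tgmap errors."""


class InfeasibleSpecError(TgmapError):
    """Requested synthetic-genome composition cannot fit the chromosome length."""


class MalformedAnnotationError(TgmapError):
    """Gene/transcript structure violates annotation invariants (e.g. CDS outside exons)."""


class UnknownChromosomeError(TgmapError):
    """A feature refers to a chromosome absent from the supplied length table."""


class OverlapError(TgmapError):
    """An insertion falls inside a planted residual element copy."""


class NoGenomicSideError(TgmapError):
    """A display product consists purely of element sequence with no genomic flank."""


class InsufficientElementEvidenceError(TgmapError):
    """A display product lacks the required element-terminus evidence at the junction."""


class FlankTooShortError(TgmapError):
    """A flank shorter than the seed length cannot be mapped (distinct from 'unmapped')."""


class UndefinedStatisticError(TgmapError):
    """A chi-square expectation of zero makes the statistic undefined."""


class ConfigError(TgmapError):
    """Pipeline configuration is invalid (missing files, bad parameter)."""


class PipelineStageError(TgmapError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
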