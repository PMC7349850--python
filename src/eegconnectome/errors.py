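"""Exception hierarchy shared across the pipeline stages."""


class EEGConnectomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EEGConnectomeError):
    """Invalid simulation or run configuration."""


class MontageError(EEGConnectomeError):
    """Unknown electrode labels or unusable sensor geometry."""


class DegenerateVarianceError(EEGConnectomeError):
    """A statistic is undefined because an input has zero variance."""


class ArtifactRejectionError(EEGConnectomeError):
    """Artifact rejection left too few usable segments."""


class PipelineStageError(EEGConnectomeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str | None, message: str):
        self.stage = stage
        self.subject_id = subject_id
        detail = f"[stage={stage}" + (f", subject={subject_id}]" if subject_id else "]")
        super().__init__(f"{detail} {message}")
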