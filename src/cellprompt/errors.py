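"""Exception hierarchy shared across the package."""


class CellPromptError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CellPromptError):
    """Malformed input file: missing column, bad value, duplicate key."""


class ResponseParseError(CellPromptError):
    """Backend response could not be parsed into the expected labels.

    Carries the raw text so a failed run remains auditable.
    """

    def __init__(self, message: str, raw_text: str = ""):
        super().__init__(message)
        self.raw_text = raw_text


class BackendError(CellPromptError):
    """A text-completion backend failed to produce a response."""


class TranscriptMissError(BackendError):
    """Replay requested for a prompt absent from the transcript store."""

    def __init__(self, digest: str):
        super().__init__(f"no recorded response for conversation digest {digest}")
        self.digest = digest


class SimulationError(CellPromptError):
    """Simulation batch could not be generated or scored."""
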