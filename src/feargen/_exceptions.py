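"""Package exception hierarchy."""


class FeargenError(Exception):
    """Base class for all feargen errors."""


class ValidationError(FeargenError, ValueError):
    """Invalid input data or configuration."""


class InfeasibleLayoutError(FeargenError, RuntimeError):
    """Glomerular placement failed: the requested density cannot satisfy the
    minimum spacing within the field after a bounded number of attempts."""


class MissingArtifactError(FeargenError, FileNotFoundError):
    """An upstream pipeline artifact is missing."""
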