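"""Package-specific exception types."""


class DegenerateChainError(ValueError):
    """Raised when a chain has no unique stationary state (multiple unit
    eigenvalues within tolerance), so stationarity-based operations are
    ill-defined."""


class GenerationExhaustedError(RuntimeError):
    """Raised when the literal trial generator hits its step cap before
    finding enough qualifying flash events."""
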