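"""Exception hierarchy shared across the package."""


class TargetoxError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TargetoxError):
    """Malformed input file; message names the offending line."""


class EmptyNetworkError(TargetoxError):
    """Filtering removed every edge."""


class DisconnectedGraphError(TargetoxError):
    """Operation requires a connected graph; run main_component first."""


class NumericalError(TargetoxError):
    """Linear-algebra failure, with condition diagnostics where available."""


class UnknownIdError(TargetoxError, KeyError):
    """An identifier was not found in the relevant index."""


class FeaturizationError(TargetoxError):
    """A drug could not be encoded (e.g. no bound protein maps to the network)."""


class InfeasibleSelectionError(TargetoxError):
    """Fewer significant neighborhoods than requested reference points."""


class StageError(TargetoxError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
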