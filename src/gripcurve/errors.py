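"""Exception hierarchy for the gripcurve pipeline."""


class GripCurveError(Exception):
    """Base class for all gripcurve errors."""


class ConfigError(GripCurveError):
    """Invalid generator or analysis configuration."""


class ParameterError(GripCurveError):
    """A processing parameter is out of its valid range (e.g. cutoff >= Nyquist)."""


class InvalidTrialError(GripCurveError):
    """A single trial fails a validity rule (no detectable onset, bad peak, ...)."""


class ParticipantExcludedError(GripCurveError):
    """A participant does not have three valid trials and is excluded."""

    def __init__(self, participant: str, reasons: list[str]):
        self.participant = participant
        self.reasons = list(reasons)
        super().__init__(f"participant {participant!r} excluded: " + "; ".join(reasons))


class SegmentationError(GripCurveError):
    """Key-instant ordering violated or a degenerate/empty segment requested."""


class DescriptorError(GripCurveError):
    """A discrete force-time descriptor is undefined for this curve."""


class InputError(GripCurveError):
    """Malformed input table (schema mismatch, non-uniform time grid, ...)."""
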