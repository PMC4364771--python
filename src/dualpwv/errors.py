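"""Exception hierarchy for the dualpwv toolkit."""


class DualPwvError(Exception):
    """Base class for all toolkit errors."""


class FormatError(DualPwvError):
    """A waveform or table file violates the expected layout."""


class ParameterError(DualPwvError):
    """An argument is outside its documented range."""


class DetectionError(DualPwvError):
    """Wave-foot detection failed on a beat (e.g. no systolic upstroke)."""


class EstimationError(DualPwvError):
    """A PWV estimate could not be formed (no surviving beats)."""


class StatisticsError(DualPwvError):
    """A statistic is undefined or degenerate for the given data."""
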