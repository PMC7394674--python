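"""Exception hierarchy for abpsim.

Every error raised by the package derives from :class:`AbpsimError` so
callers can catch simulator problems without swallowing programming errors.
"""


class AbpsimError(Exception):
    """Base class for all abpsim errors."""


class ScenarioError(AbpsimError):
    """A vitals scenario is malformed, unordered, empty or sampled out of range."""


class VitalsError(AbpsimError):
    """A vitals sample violates the physiological contract (e.g. SBP <= DBP)."""


class TemplateError(AbpsimError):
    """A pulse template is degenerate, too short, or fails its invariants."""


class EngineError(AbpsimError):
    """The waveform pipeline cannot run (bad config, buffer deadlock, ...)."""


class SinkError(AbpsimError):
    """An output sink rejected samples."""


class HardwareUnavailableError(AbpsimError):
    """A physical DAC driver was requested but none is installed."""


class AnalysisError(AbpsimError):
    """The contour analyzer cannot produce a result (too few beats, ...)."""
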