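"""Exception hierarchy for paddysim."""


class PaddysimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PaddysimError):
    """Invalid configuration value (season spec, policy fraction, prior bounds...)."""


class UnrecoverableRecordError(PaddysimError):
    """A missing weather value cannot be imputed from the available record."""


class WindowBoundsError(PaddysimError):
    """A stage window falls outside the span of the weather series."""


class TruncatedSeasonError(PaddysimError):
    """Weather series ends before the crop reaches maturity or the harvest cap."""


class ForcingError(PaddysimError):
    """Non-finite or negative meteorological forcing passed to the simulator."""


class DegenerateCalibrationError(PaddysimError):
    """All likelihood weights vanished; the calibration carries no information."""


class FitFailureError(PaddysimError):
    """A candidate response-curve fit failed to converge."""


class EmptySelectionError(PaddysimError):
    """Model selection was asked to choose among zero candidate fits."""


class DegenerateBaselineError(PaddysimError):
    """Full-irrigation reference yield is non-positive; ratios are undefined."""


class PipelineStageError(PaddysimError):
    """A pipeline stage failed; carries the stage name and offending key."""

    def __init__(self, stage: str, key, message: str):
        self.stage = stage
        self.key = key
        super().__init__(f"stage '{stage}' failed for {key!r}: {message}")
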