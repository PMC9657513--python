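"""Exception hierarchy.

Two branches matter operationally: :class:`FrameIOError` (file/format
problems, CLI exit code 2) and :class:`AnalysisError` (the measurement
itself cannot proceed, CLI exit code 3).
"""


class ThermolesionError(Exception):
    """Base class for all package errors."""


class FrameIOError(ThermolesionError, OSError):
    """A thermal frame could not be read or written."""


class AnalysisError(ThermolesionError, ValueError):
    """An analysis step received input it cannot process."""


class CalibrationError(AnalysisError):
    """Sensor-count calibration could not be fitted."""


class SegmentationError(AnalysisError):
    """Histogram or threshold computation failed (e.g. no bimodality)."""


class ContourError(AnalysisError):
    """Isotherm extraction or polygon-area computation failed."""


class MeasurementError(AnalysisError):
    """Lesion core/surround statistics could not be computed."""
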