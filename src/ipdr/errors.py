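"""Exception hierarchy for the IPDR pipeline.

Every stage raises a subclass of :class:`IPDRError` so that the pipeline
driver can abort with the stage name and the offending record.
"""


class IPDRError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IPDRError):
    """Input file does not have the declared columns/layout."""


class DataError(IPDRError):
    """Input data violates a contract (non-monotone time, long NaN runs...)."""


class CalibrationError(IPDRError):
    """Static-interval calibration rejected (too short, too noisy, bad gravity)."""


class PlanError(IPDRError):
    """A synthetic gait plan is infeasible (e.g. stride too short for the rate)."""


class SegmentationError(IPDRError):
    """Stride segmentation cannot run (signal/stride too short)."""


class EventError(IPDRError):
    """Gait-event detection failed (no swing peak, portion too short)."""


class NumericError(IPDRError):
    """Numerical failure (non-finite samples, covariance lost definiteness)."""


class PipelineError(IPDRError):
    """A pipeline stage failed; message names the stage."""
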