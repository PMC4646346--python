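"""Exception hierarchy.

Plain ``ValueError`` is used for invalid arguments; the classes here mark
failure modes a caller may reasonably want to catch and handle separately.
"""


class VentmechError(Exception):
    """Base class for package-specific failures."""


class ConvergenceError(VentmechError):
    """An iterative calibration failed to reach its target.

    Attributes
    ----------
    achieved : float
        The best value reached before giving up.
    """

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


class InfeasibleDesignError(VentmechError):
    """A waveform design request cannot be satisfied.

    Attributes
    ----------
    achieved : int
        Number of tones that could be placed.
    """

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


class DegenerateClusteringError(VentmechError):
    """Fewer distinct intensity values than requested clusters."""


class EmptySignalError(VentmechError):
    """All corrected intensities are zero; no signal to normalize."""


class IllConditionedBinError(VentmechError):
    """Flow spectral coefficient too small at a forcing frequency."""


class DegenerateTestError(VentmechError):
    """A t-test with zero-variance input (e.g. identical paired samples)."""


class UndefinedCorrelationError(VentmechError):
    """Pearson correlation of a zero-variance variable."""


class InsufficientDataError(VentmechError):
    """Too few usable rows after filtering/exclusion rules."""


class SchemaError(VentmechError):
    """A tabular file is missing required columns."""


class SamplingError(VentmechError):
    """A recording's time axis is not uniformly sampled."""


class FormatError(VentmechError):
    """An input file could not be parsed."""
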