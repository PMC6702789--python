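"""Exception and warning types used across the package."""


class SlfomapError(Exception):
    """Base class for all slfomap errors."""


class InvalidSpecError(SlfomapError, ValueError):
    """A phantom specification violates its invariants."""


class InvalidBandError(SlfomapError, ValueError):
    """A filter band is empty, inverted, or extends past Nyquist."""


class RecordTooShortError(SlfomapError, ValueError):
    """A timecourse is too short for the requested operation."""


class EmptyMaskError(SlfomapError, ValueError):
    """A mask or ROI selects no voxels."""


class WindowError(SlfomapError, ValueError):
    """A lag search window is invalid for the record length."""


class NullDistributionError(SlfomapError, ValueError):
    """A null distribution cannot support the requested quantile."""


class SidelobeWarning(UserWarning):
    """The probe autocorrelation has large sidelobes inside the search window."""


class MisuseWarning(UserWarning):
    """Inputs look degenerate for the requested analysis (e.g. matched
    records passed to the mismatched-regressor null)."""


class ConvergenceWarning(UserWarning):
    """Iterative refinement stopped without meeting its tolerance."""
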