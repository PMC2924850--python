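"""Exception hierarchy.

Everything raised on purpose derives from :class:`CinefillError` so callers
can catch package failures without masking programming errors.
"""


class CinefillError(Exception):
    """Base class for all cinefill errors."""


class UnknownGradeError(CinefillError, ValueError):
    """A diastolic-dysfunction grade label is not one of the known labels."""


class InfeasibleParametersError(CinefillError, ValueError):
    """Generator parameters cannot produce a physically valid patient."""


class DegenerateCurveError(CinefillError, ValueError):
    """A volume curve carries no usable systole/diastole (e.g. flat curve)."""


class NoFillingError(CinefillError, ValueError):
    """No positive filling rate was found during diastole."""


class RecoveryTargetError(CinefillError, ValueError):
    """The requested volume-recovery target is never reached in diastole."""


class SeedPointError(CinefillError, ValueError):
    """A segmentation seed point lies outside the image or the blood pool."""


class CalibrationError(CinefillError, ValueError):
    """Threshold calibration cannot reach the requested specificity."""
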