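"""Exception hierarchy shared across the package."""


class BrachyChoiceError(Exception):
    """Base class for all package-specific errors."""


class MissingTarget(BrachyChoiceError):
    """No HR-CTV (or the CTV union is empty) where a target volume is required."""


class MissingTandem(BrachyChoiceError):
    """The structure set carries no digitized central tandem."""


class MalformedTandem(BrachyChoiceError):
    """Tandem polyline is too short or not strictly ordered along the SI axis."""


class DegenerateContour(BrachyChoiceError):
    """A planar contour with fewer than three vertices."""


class ShapeError(BrachyChoiceError):
    """Input volume shape incompatible with the network's conv/pool chain."""


class ClassMissing(BrachyChoiceError):
    """An operation requiring both applicator classes saw only one."""


class SmoteError(BrachyChoiceError):
    """Minority class too small to synthesize from."""


class FoldError(BrachyChoiceError):
    """Cannot form the requested number of patient-level folds."""


class TrainingDiverged(BrachyChoiceError):
    """Loss became non-finite during optimization."""


class InputError(BrachyChoiceError):
    """Mismatched or invalid evaluation inputs."""


class FitError(BrachyChoiceError):
    """Grid search exhausted without a valid classifier fit."""


class PhantomError(BrachyChoiceError):
    """Requested synthetic anatomy is geometrically infeasible."""
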