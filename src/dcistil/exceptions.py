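"""Exception hierarchy for the dcistil pipeline."""


class DcisTilError(Exception):
    """Base class for all dcistil errors."""


class InvalidSpecError(DcisTilError, ValueError):
    """A synthetic-tile or cohort-simulation specification is invalid."""


class InvalidAnnotationError(DcisTilError, ValueError):
    """A duct annotation polygon is degenerate or self-intersecting."""


class DegenerateStainError(DcisTilError, ValueError):
    """Stain vectors are (near-)collinear and cannot be unmixed."""


class DimensionMismatchError(DcisTilError, ValueError):
    """Two arrays that must share a shape do not."""


class NoDcisError(DcisTilError, ValueError):
    """No annotated DCIS region is present; the patient is not evaluable."""


class DegeneratePatchError(DcisTilError, ValueError):
    """Requested patch size is below the image resolution floor."""


class NotEvaluableError(DcisTilError, ValueError):
    """A score or threshold cannot be computed from the available data."""


class InsufficientDataError(DcisTilError, ValueError):
    """Too few observations for the requested statistic."""


class UnknownFieldError(DcisTilError, KeyError):
    """A requested covariate is not a column of the cohort table."""


class NonNestedModelError(DcisTilError, ValueError):
    """Likelihood-ratio comparison requested for non-nested models."""


class UndefinedORError(DcisTilError, ValueError):
    """No exposure-discordant matched set; the matched OR is undefined."""


class ModelConvergenceError(DcisTilError, RuntimeError):
    """A model fit failed to converge; carries the fitting trace message."""
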