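"""Exception types shared across the pipeline."""


class ExposcanError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ExposcanError, ValueError):
    """A generator or pipeline configuration violates its invariants."""


class DimensionError(ExposcanError, ValueError):
    """Inputs that must be aligned (rows, flags, columns) are not."""


class ConstantCovariateError(ExposcanError, ValueError):
    """A covariate carries no information (zero variance)."""


class MonotoneLikelihoodError(ExposcanError, RuntimeError):
    """The Cox partial likelihood has no finite maximizer (perfect
    separation of events by a covariate)."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(
            f"monotone partial likelihood: covariate {covariate!r} separates "
            "events from non-events; no finite coefficient exists"
        )


class DegenerateScoreError(ExposcanError, ValueError):
    """A score has zero variance and cannot be standardized or cut."""


class InsufficientInstrumentsError(ExposcanError, ValueError):
    """Too few SNPs survive instrument selection for MR."""


class DependencyError(ExposcanError, RuntimeError):
    """A pipeline stage was enabled without its upstream outputs."""
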