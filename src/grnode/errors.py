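"""Exception hierarchy for grnode."""


class GRNodeError(Exception):
    """Base class for all grnode-specific errors."""


class DegenerateSeriesError(GRNodeError):
    """A gene series is constant after centering and cannot be scaled."""

    def __init__(self, gene: str):
        self.gene = gene
        super().__init__(
            f"degenerate series: gene {gene!r} is constant after centering "
            "(zero range); reject it before standardisation"
        )


class UnidentifiableStructureError(GRNodeError):
    """The weighted regression design is rank deficient for a candidate structure."""


class UnstableSubmodelError(GRNodeError):
    """A sub-model has a non-negative diagonal coefficient (no steady state)."""


class IntegrationFailureError(GRNodeError):
    """The ODE solver failed to produce a trajectory."""


class ConfigError(GRNodeError):
    """Invalid configuration value or unknown configuration key."""


class PriorFormatError(GRNodeError):
    """Malformed prior-knowledge table."""
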