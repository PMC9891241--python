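"""Exception hierarchy for gqscore."""


class GQSError(Exception):
    """Base class for all gqscore errors."""


class ConfigError(GQSError):
    """A configuration problem, e.g. a required column role cannot be resolved."""


class InputError(GQSError):
    """Malformed or empty input data."""


class VariantLookupError(GQSError, KeyError):
    """A requested variant ID is absent from the panel or summary statistics."""

    def __str__(self) -> str:  # KeyError quotes its argument; keep the message readable
        return Exception.__str__(self)


class DegenerateRegionError(GQSError):
    """The region cannot anchor a regression line (index SNP has P = 1)."""


class EmptyRegionError(GQSError):
    """A targeted region contains no summary-statistic records."""


class SimulationError(GQSError):
    """The simulator was asked for an impossible configuration."""
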