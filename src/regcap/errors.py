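"""Exception hierarchy for regcap."""


class RegcapError(Exception):
    """Base class for all regcap errors."""


class SchemaError(RegcapError):
    """Invalid indicator schema (duplicate ids, unknown dimension, bad nature)."""


class PanelError(RegcapError):
    """Invalid raw panel (unknown keys, duplicate rows, bad categories)."""


class PreprocessingError(RegcapError):
    """Interpolation / normalization failure (e.g. a fully missing series)."""


class WeightError(RegcapError):
    """Invalid or degenerate weight computation."""


class AnovaError(RegcapError):
    """Degenerate one-way ANOVA (undersized group, zero within-group variance)."""


class SimulationError(RegcapError):
    """Invalid synthetic-data configuration."""
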