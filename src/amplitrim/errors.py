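"""Exception hierarchy shared across the package."""


class AmplitrimError(Exception):
    """Base class for all errors raised by amplitrim."""


class PanelFormatError(AmplitrimError):
    """Malformed primer table (bad field count, illegal characters, ...)."""


class PanelValidationError(AmplitrimError):
    """Structurally valid table violating panel invariants (duplicate ids, ...)."""


class IndexConfigError(AmplitrimError):
    """Invalid k-mer index configuration, e.g. k longer than the shortest primer."""


class FastqFormatError(AmplitrimError):
    """Truncated or inconsistent FASTQ record."""


class SimulationError(AmplitrimError):
    """Simulator could not satisfy its constraints (e.g. primer separation)."""


class EvaluationError(AmplitrimError):
    """Trim results could not be joined against the truth table."""
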