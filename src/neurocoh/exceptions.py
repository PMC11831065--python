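"""Exception hierarchy for the neurocoh pipeline.

Errors are grouped so that the CLI can map them onto distinct exit codes:
configuration problems, data/contract problems, and numerical degeneracies.
"""


class NeurocohError(Exception):
    """Base class for all neurocoh errors."""


class ConfigurationError(NeurocohError):
    """A config object violates its invariants (bad band, bad rate, ...)."""


class DataError(NeurocohError):
    """Input data violates a contract (missing annotations, channel mismatch, ...)."""


class NumericalError(NeurocohError):
    """A quantity is undefined on the given input (zero power, zero variance, ...)."""
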