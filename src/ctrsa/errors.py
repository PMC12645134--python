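"""Exception hierarchy.

The CLI maps these onto exit codes (config -> 2, data -> 3, convergence -> 4),
so library code should raise the most specific class that applies.
"""


class CtrsaError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(CtrsaError):
    """Invalid configuration: bad phantom spec, impossible geometry, bad options."""


class FieldOfViewError(ConfigError):
    """A posed shape would leave the simulated scanner field of view."""


class DataError(CtrsaError):
    """Invalid or degenerate input data: empty masks, missing labels, bad files."""


class ConvergenceError(CtrsaError):
    """A registration failed to converge."""
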