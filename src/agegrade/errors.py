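"""Exception hierarchy for the age-grading pipeline.

Each stage raises a specific subclass so the CLI can map error classes to
distinct exit codes.
"""


class AgegradeError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(AgegradeError):
    """Invalid configuration value; the message names the offending field."""

    exit_code = 2


class InputError(AgegradeError):
    """Malformed or empty input (bad CSV, negative fluorescence, p outside [0,1])."""

    exit_code = 3


class DataError(AgegradeError):
    """Structurally valid input that violates a data contract (missing
    reference gene, unknown sample, excess degenerate bootstrap resamples)."""

    exit_code = 4


class DesignError(AgegradeError):
    """Experimental design insufficient for the requested analysis
    (e.g. a single replicate per cell with an interaction term)."""

    exit_code = 5


class ModelError(AgegradeError):
    """Model cannot be fitted (constant age, degenerate variate)."""

    exit_code = 6


class CollinearityError(ModelError):
    """Gene columns are linearly dependent; the message names them."""

    exit_code = 7


class InvertibilityError(ModelError):
    """Calibration slope too close to zero to invert for age."""

    exit_code = 8
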