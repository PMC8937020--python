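"""Exception hierarchy shared across the pipeline.

Each class carries the process exit code the CLI maps it to.
"""


class MethpipeError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigurationError(MethpipeError):
    """Invalid configuration value, unknown key, or infeasible parameter."""

    exit_code = 2


class DataFormatError(MethpipeError):
    """Malformed or inconsistent input data (bad scores, coordinates, missing genes)."""

    exit_code = 3


class DegenerateStatisticsError(MethpipeError):
    """A statistic is undefined on the given data (constant vector, zero variance, empty margin)."""

    exit_code = 4
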