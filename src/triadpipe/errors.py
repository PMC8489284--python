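"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation/configuration problems
exit with 2, statistical preconditions with 3.
"""


class TriadpipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TriadpipeError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(TriadpipeError, ValueError):
    """Malformed input data (sequences, tables, headers)."""


class StatisticsError(TriadpipeError, ValueError):
    """A statistical routine was called on data that cannot support it."""


class AssignmentConflictError(TriadpipeError):
    """Locus-unique peptides of one protein span multiple homoeolog families."""
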