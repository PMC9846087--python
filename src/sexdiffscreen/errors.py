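"""Exception hierarchy shared across the pipeline stages.

Errors are split into three families so that callers (and the CLI exit
codes) can distinguish misconfiguration from malformed data from
statistically degenerate inputs.
"""


class SexdiffError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SexdiffError):
    """A dialect, config file or argument combination is invalid."""


class DataError(SexdiffError):
    """Input data violate a contract (bad values, duplicates, mismatches)."""


class ValidationError(DataError):
    """A record failed field-level validation; names the offending row."""


class DuplicateSnpError(DataError):
    """The same SNP id appears more than once within one table."""


class IncompatibleVariantError(DataError):
    """Allele sets of a SNP cannot be reconciled between strata."""


class LookupError_(DataError):
    """A requested SNP, gene or group is absent from the data."""


class DegenerateStatisticsError(SexdiffError):
    """The requested test is undefined for these inputs (zero variance,
    empty strata, too few groups or replicates)."""
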