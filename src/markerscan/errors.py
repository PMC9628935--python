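"""Exception hierarchy for markerscan.

Every anticipated failure mode raises a subclass of :class:`MarkerscanError`
so callers (and the CLI) can distinguish usage/data errors from bugs.
"""


class MarkerscanError(Exception):
    """Base class for all markerscan errors."""


class FastaFormatError(MarkerscanError):
    """Malformed FASTA input; message names the offending line."""


class SchemaError(MarkerscanError):
    """Metadata table violates the expected column schema."""


class DuplicateRecordError(MarkerscanError):
    """Duplicate sequence id or duplicate (strain, locus) row."""


class LookupResolutionError(MarkerscanError):
    """A (fasta_path, seq_id) reference in the metadata cannot be resolved."""


class LengthMismatchError(MarkerscanError):
    """Sequences expected to be equal length are not."""


class UndefinedStatisticError(MarkerscanError):
    """A statistic is mathematically undefined for the given input
    (e.g. typing efficiency of a monomorphic locus)."""


class SimulationError(MarkerscanError):
    """The synthetic-data generator cannot satisfy its contract."""


class ConfigError(MarkerscanError):
    """Invalid simulation or run configuration."""
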