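"""Exception hierarchy.

DataError covers malformed or inconsistent user-supplied data (exit code 2
at the CLI); EngineError covers internal map/collate/reduce failures,
including callback exceptions (re-raised with item/key context) and spill
I/O faults.
"""


class ClusterwormError(Exception):
    """Base class for package errors."""


class DataError(ClusterwormError):
    """Malformed input data (bad FASTA/FASTQ record, invalid characters,
    inconsistent intermediate tables)."""


class ConsistencyError(DataError):
    """Cross-table inconsistency: an edge endpoint without a zone, a k-mer
    without an abundance, tables built with different parameters."""


class EngineError(ClusterwormError):
    """Failure inside the map/collate/reduce engine (callback error with
    context attached, or spill-file I/O)."""
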