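"""Exception hierarchy.

``DataError`` covers malformed or inconsistent input data (exit code 1 in the
CLI); ``ConfigError`` covers invalid run configuration (exit code 2).
"""


class NickeditError(Exception):
    """Base class for all package errors."""


class DataError(NickeditError):
    """Malformed or inconsistent input data (FASTA/FASTQ/TSV contents)."""


class ConfigError(NickeditError):
    """Invalid run configuration (unknown keys, missing files, bad values)."""
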