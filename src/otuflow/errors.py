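"""Exception types shared across the package."""


class OtuflowError(Exception):
    """Base class for all package errors."""


class ParseError(OtuflowError):
    """Malformed FASTQ/FASTA/TSV input."""


class EncodingError(ParseError):
    """Quality string not encodable as Sanger Phred+33."""


class PairingError(OtuflowError):
    """Forward/reverse streams out of register."""


class ConsistencyError(OtuflowError):
    """Internal bookkeeping violated (count totals, stage continuity)."""


class SpecValidationError(OtuflowError):
    """Simulation or pipeline configuration fails validation."""
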