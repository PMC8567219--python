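"""Exception hierarchy shared across the pipeline stages."""


class PhosphoflowError(Exception):
    """Base class for all package errors."""


class ConfigError(PhosphoflowError):
    """Invalid simulation or pipeline configuration."""


class FormatError(PhosphoflowError):
    """Malformed input table or FASTA (missing column, duplicate id, ...)."""


class NormalizationError(PhosphoflowError):
    """A normalization group cannot be fitted (no reference peptides)."""


class AssemblyError(PhosphoflowError):
    """Site assembly failure, e.g. evidence residue disagrees with the FASTA."""
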