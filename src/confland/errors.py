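"""Typed exceptions shared across the package."""


class ConflandError(Exception):
    """Base class for all package errors."""


class FormatError(ConflandError):
    """A file (A3M/FASTA/PDB/manifest) violates the expected format."""


class ArgumentError(ConflandError, ValueError):
    """An operation received an invalid argument."""


class SelectionError(ConflandError):
    """A residue selection does not resolve on a structure."""


class PredictionError(ConflandError):
    """A structure predictor failed on a job."""


class PredictorUnavailableError(PredictionError):
    """The requested predictor backend is not available on this host."""


class RuleConfigError(ConflandError):
    """A mock-predictor rule table cannot resolve a job."""
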