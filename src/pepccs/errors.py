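"""Exception hierarchy for pepccs."""


class PepCCSError(Exception):
    """Base class for all pepccs errors."""


class InvalidSequenceError(PepCCSError):
    """A residue letter outside the supported alphabet was encountered."""


class UnsupportedModificationError(PepCCSError):
    """A modification other than N-terminal acetylation or Met oxidation."""


class InvalidChargeError(PepCCSError):
    """Charge state outside the supported set {2, 3, 4}."""


class EncodingLengthError(PepCCSError):
    """Peptide too long for the configured fixed encoding length."""


class ConfigurationError(PepCCSError):
    """Inconsistent network / featurization configuration."""


class IncompatibleEncodingError(PepCCSError):
    """Featurization config hash mismatch between model and encoded data."""


class TrainingDivergedError(PepCCSError):
    """Loss became non-finite during optimization."""


class DatasetFormatError(PepCCSError):
    """A mandatory column is missing or the file is unreadable."""


class DegenerateInputError(PepCCSError):
    """Input does not admit the requested statistic (e.g. zero variance)."""
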