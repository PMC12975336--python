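"""Exception hierarchy shared across the package."""


class DrugMRError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DrugMRError):
    """A summary-statistics file does not conform to the requested dialect."""


class EmptyDatasetError(DrugMRError):
    """A file or dataset contained no usable association records."""


class EmptyIntersectionError(DrugMRError):
    """Two datasets share no variants at the positional level."""


class NoInstrumentsError(DrugMRError):
    """Instrument selection left nothing to analyse."""


class DegeneratePanelError(DrugMRError):
    """Every reference-panel variant is monomorphic."""


class CollinearityError(DrugMRError):
    """The multivariable exposure design is rank deficient."""


class InsufficientInstrumentsError(DrugMRError):
    """An estimator needs more instruments than were supplied."""


class NumericalError(DrugMRError):
    """A linear-algebra step failed beyond repair (singular weight matrix)."""


class ConfigError(DrugMRError):
    """A simulation or pipeline configuration is internally inconsistent."""
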