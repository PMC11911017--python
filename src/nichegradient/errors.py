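"""Exception hierarchy for the gradient-niche pipeline."""


class NicheGradientError(Exception):
    """Base class for all package errors."""


class FormatError(NicheGradientError):
    """Input file does not have the expected layout (missing columns etc.)."""


class ParseError(NicheGradientError):
    """A cell could not be parsed; the message names the offending row/column."""


class ConfigurationError(NicheGradientError):
    """Variable-domain registry or analysis configuration is inconsistent."""


class DegenerateSampleError(NicheGradientError):
    """All values identical — no histogram can be built."""


class CombinationExcluded(NicheGradientError):
    """No pair of bins differs significantly; the combination is dropped."""


class FitFailureError(NicheGradientError):
    """Logistic-polynomial fit failed even after degree reductions."""
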