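"""Exception hierarchy."""


class InfodynError(Exception):
    """Base class for all package errors."""


class ParameterError(InfodynError, ValueError):
    """Invalid parameter value or combination."""


class FormatError(InfodynError, ValueError):
    """Malformed or incomplete on-disk recording container."""


class DegenerateSignalError(InfodynError, ValueError):
    """Signal is constant or otherwise unusable for the requested operation."""


class EstimatorError(InfodynError, ValueError):
    """Estimator preconditions violated (sample size, coincidences, ...)."""
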