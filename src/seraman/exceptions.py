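"""Exception hierarchy.

Everything raised on purpose derives from :class:`SeramanError`, so
callers can catch one type at the pipeline boundary.
"""


class SeramanError(Exception):
    """Base class for all errors raised by seraman."""


class SpectraParseError(SeramanError):
    """A spectra file contained a row that does not parse."""


class DuplicateRecordError(SeramanError):
    """Duplicate (sample, point, wavenumber) records in the input."""


class AxisError(SeramanError):
    """Wavenumber axes disagree or are not strictly increasing."""


class ExtrapolationError(SeramanError):
    """Requested grid extends beyond the measured wavenumber range."""


class ParameterError(SeramanError):
    """A parameter violates its documented constraints."""


class DegenerateDataError(SeramanError):
    """Input data has no usable variance (constant spectrum, zero pooled
    variance, single-class labels, ...)."""


class RatiometricError(SeramanError):
    """The denominator peak of a sample is non-positive."""


class ConfigError(SeramanError):
    """A run or simulation configuration is inconsistent."""
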