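"""Exception types shared across the pipeline."""


class LfpWavesError(Exception):
    """Base class for all package-specific errors."""


class InvalidBandError(LfpWavesError, ValueError):
    """Band edges fall outside (0, fs/2) or are not ordered."""


class InsufficientDataError(LfpWavesError, ValueError):
    """Signal too short for the requested operation."""


class UndefinedCorrelationError(LfpWavesError, ValueError):
    """A correlation is requested on a map with zero circular variance."""


class LibraryDegeneracyError(LfpWavesError, RuntimeError):
    """A reference-library entry has no fingerprint coefficient above chance."""


class ConfigurationError(LfpWavesError, ValueError):
    """A run configuration references missing files or inconsistent options."""
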