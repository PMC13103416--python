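"""Exception types shared across the package."""


class BudfreezeError(Exception):
    """Base class for all package-specific errors."""


class WeatherValidationError(BudfreezeError):
    """Malformed or physically inconsistent daily weather input."""


class SeasonGapError(BudfreezeError):
    """A dormant season used for simulation has missing days."""


class UnsupportedLatitudeError(BudfreezeError):
    """Latitude outside the supported range (Southern Hemisphere or polar)."""


class AlignmentError(BudfreezeError):
    """Chill, weather and hardiness series are not aligned on the same dates."""


class DegenerateSpreadError(BudfreezeError):
    """Percentile cold-hardiness values collapsed; damage interpolation undefined."""


class ParameterError(BudfreezeError):
    """Unknown cultivar/percentile or inconsistent parameter table."""


class ConfigError(BudfreezeError):
    """Invalid run configuration."""
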