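"""Exceptions signalling the pipeline's defined refusal modes.

These are contract outcomes, not crashes: the processing chain raises them
when the physics says no trustworthy answer exists (e.g. the cardiac
fundamental coincides with a breathing harmonic), and the pipeline driver
converts them into report flags / exit statuses.
"""


class RadarVitalsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RadarVitalsError):
    """A configuration value violates a documented bound."""


class BreathHold(RadarVitalsError):
    """Breathing-band displacement below the breath-hold floor; BR undefined."""


class NoCardiacFound(RadarVitalsError):
    """Every candidate mode is an integer multiple of the breathing rate."""


class ReconstructionRefused(RadarVitalsError):
    """Fewer than two usable harmonics: the cardiac waveform cannot be
    reconstructed."""


class InsufficientBeats(RadarVitalsError):
    """Too few detected valleys in the analysis window for IBI/HRV work."""
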