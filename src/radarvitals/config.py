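"""Waveform, motion-compensation and pipeline configuration.

The radar defaults describe a 60 GHz FMCW sensor behind a seat back:
5 GHz sweep bandwidth (3 cm range resolution), 64 fast-time samples at
1 MHz, 32 chirps per frame averaged for phase-noise suppression, and a
20 Hz frame rate chosen as twice the highest vibration frequency of
interest (10 Hz).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigError

#: speed of light in free space, m/s
C_LIGHT = 299_792_458.0


@dataclass(frozen=True)
class RadarConfig:
    """FMCW waveform parameters and derived geometry.

    Parameters
    ----------
    f_min : float
        Sweep start frequency in Hz.
    bandwidth : float
        Sweep bandwidth ``BW = f_max - f_min`` in Hz.  The chirp duration is
        derived as ``T = BW / slope``.
    slope : float
        Chirp slope ``K`` in Hz/s.
    sample_rate : float
        Fast-time ADC rate in Hz.
    samples_per_chirp : int
        Fast-time samples per chirp; the one-sided range spectrum has
        ``samples_per_chirp // 2`` bins.
    chirps_per_frame : int
        Chirps averaged per frame to suppress phase noise.
    prf : float
        Pulse repetition (frame) frequency in Hz; must be at least twice the
        highest modelled vibration frequency.
    idle_time : float
        Inter-chirp idle time in s (bookkeeping only; displacement is
        treated as constant within a frame).
    """

    f_min: float = 58e9
    bandwidth: float = 5e9
    slope: float = 78.128e12
    sample_rate: float = 1e6
    samples_per_chirp: int = 64
    chirps_per_frame: int = 32
    prf: float = 20.0
    idle_time: float = 5e-6
    max_vibration_freq: float = 10.0

    def __post_init__(self) -> None:
        if self.samples_per_chirp < 2:
            raise ConfigError("samples_per_chirp must be >= 2")
        if self.bandwidth <= 0 or self.slope <= 0:
            raise ConfigError("bandwidth and slope must be positive")
        if self.sample_rate <= 0 or self.prf <= 0:
            raise ConfigError("sample_rate and prf must be positive")
        if self.prf < 2.0 * self.max_vibration_freq:
            raise ConfigError(
                f"prf {self.prf} Hz below Nyquist for "
                f"{self.max_vibration_freq} Hz vibrations"
            )

    @property
    def chirp_duration(self) -> float:
        """Sweep time ``T = BW / K`` in s."""
        return self.bandwidth / self.slope

    @property
    def range_resolution(self) -> float:
        """Range bin width ``c / (2 BW)`` in m."""
        return C_LIGHT / (2.0 * self.bandwidth)

    @property
    def center_wavelength(self) -> float:
        """Wavelength at the sweep centre frequency, m (~4.93 mm here).

        The slow-time phase of a range-FFT peak tracks target motion at the
        sweep centre frequency (carrier phase plus half the beat-frequency
        ramp across the chirp), so this is the displacement scale.
        """
        return C_LIGHT / (self.f_min + self.bandwidth / 2.0)

    @property
    def n_range_bins(self) -> int:
        """One-sided range-spectrum size."""
        return self.samples_per_chirp // 2

    @property
    def max_range(self) -> float:
        """Largest unambiguous range, ``n_range_bins * range_resolution`` m."""
        return self.n_range_bins * self.range_resolution

    @property
    def frame_period(self) -> float:
        return 1.0 / self.prf

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class MotionConfig:
    """Body-movement compensation settings.

    ``derivative_threshold`` is the spike threshold on the per-frame first
    difference of displacement, in mm per slow-time sample (0.48 mm/sample,
    an empirical mean + 3 SD bound over clean seated-breathing steps).
    ``sigma_multiplier`` scales the cross-bin outlier band: per-bin summary
    values outside mean +/- sigma_multiplier * SD are discarded.
    """

    derivative_threshold: float = 0.48
    sigma_multiplier: float = 1.0
    interpolate_spikes: bool = False
    #: extra steps zeroed on each side of a super-threshold step; movement
    #: artifacts rise and fall through the threshold, so their sub-threshold
    #: tails belong to the same event
    spike_dilation: int = 3

    def __post_init__(self) -> None:
        if self.derivative_threshold <= 0:
            raise ConfigError("derivative_threshold must be positive")
        if self.sigma_multiplier <= 0:
            raise ConfigError("sigma_multiplier must be positive")
        if self.spike_dilation < 0:
            raise ConfigError("spike_dilation must be >= 0")


@dataclass(frozen=True)
class VMDConfig:
    """Variational-mode-decomposition settings (see :mod:`radarvitals.vmd`)."""

    n_modes: int = 10
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init: str = "grid"

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ConfigError("n_modes must be >= 1")
        if self.alpha <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ConfigError("invalid VMD parameters")
        if self.init not in ("grid", "zero", "random"):
            raise ConfigError(f"unknown VMD init {self.init!r}")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end processing configuration for the seat-radar chain."""

    radar: RadarConfig = field(default_factory=RadarConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    vmd: VMDConfig = field(default_factory=VMDConfig)
    # slow-time range bins carrying the seated torso (12-27 cm at 3 cm bins)
    torso_bins: tuple[int, ...] = (4, 5, 6, 7, 8, 9)
    breathing_band: tuple[float, float] = (0.1, 0.8)
    cardiac_band: tuple[float, float] = (0.8, 6.0)
    #: breath-hold preset narrows the cardiac band to 0.8-3 Hz
    breath_hold_cardiac_band: tuple[float, float] = (0.8, 3.0)
    breath_hold_floor_mm: float = 0.15
    #: cardiac-band RMS below this holds no heartbeat, only noise floor
    cardiac_floor_mm: float = 0.002
    harmonic_tolerance_hz: float = 0.05
    harmonic_tolerance_rel: float = 0.03
    max_harmonic_order: int = 4
    valley_match_window_s: float = 0.25
    use_vmd: bool = True

    def __post_init__(self) -> None:
        for name in ("breathing_band", "cardiac_band", "breath_hold_cardiac_band"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo < hi):
                raise ConfigError(f"{name}: need 0 < low < high, got {(lo, hi)}")
            if hi >= self.radar.prf / 2.0:
                raise ConfigError(
                    f"{name} upper edge {hi} Hz not below Nyquist "
                    f"{self.radar.prf / 2.0} Hz"
                )
        if not self.torso_bins:
            raise ConfigError("torso_bins must not be empty")
        if min(self.torso_bins) < 0 or max(self.torso_bins) >= self.radar.n_range_bins:
            raise ConfigError("torso_bins outside the one-sided range spectrum")
        if self.harmonic_tolerance_hz <= 0 or self.harmonic_tolerance_rel < 0:
            raise ConfigError("harmonic tolerances must be positive")
        if self.max_harmonic_order < 2:
            raise ConfigError("max_harmonic_order must be >= 2")

    def harmonic_tolerance(self, freq: float) -> float:
        """Frequency tolerance used when testing integer-multiple relations."""
        return max(self.harmonic_tolerance_hz, self.harmonic_tolerance_rel * freq)

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        for name, sub_cls in (("radar", RadarConfig), ("motion", MotionConfig), ("vmd", VMDConfig)):
            if name in data:
                sub = data.pop(name)
                _check_keys(sub, sub_cls, name)
                kwargs[name] = sub_cls(**sub)
        _check_keys(data, cls, "pipeline")
        for name in ("torso_bins", "breathing_band", "cardiac_band", "breath_hold_cardiac_band"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**kwargs, **data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _check_keys(data: dict[str, Any], cls: type, where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {where} config keys: {sorted(unknown)}")
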