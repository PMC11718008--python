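"""End-to-end processing: raw cube -> vitals report.

Stage order: DC removal -> chirp averaging -> fast-time FFT -> multi-bin
phase extraction and unwrapping -> body-movement compensation -> breathing
estimation (0.1-0.8 Hz) -> cardiac band (0.8-6 Hz) -> VMD -> harmonic
selection / reconstruction -> valley detection -> cross-bin fusion ->
IBI/HR/HRV and morphology.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .cardiac import bandpass_cardiac, reconstruct, select_harmonics
from .config import PipelineConfig
from .errors import (BreathHold, InsufficientBeats, NoCardiacFound,
                     ReconstructionRefused)
from .motion import compensate_movement
from .range_processing import BinDisplacementSet, cube_to_displacement
from .respiration import estimate_br
from .synthetic import RadarCube
from .vitals import (VitalsReport, classify_morphology, compute_hrv,
                     detect_valleys, fuse_bins)
from .vmd import vmd_decompose

__all__ = ["PipelineResult", "run_pipeline", "process_displacements"]

log = logging.getLogger("radarvitals")


@dataclass
class PipelineResult:
    report: VitalsReport
    displacements: BinDisplacementSet | None = None
    compensated: np.ndarray | None = None
    per_bin_waveforms: list = field(default_factory=list)
    per_bin_valleys: list = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)

    @property
    def status(self) -> str:
        """'ok', 'refused' or 'breath_hold' for exit-status mapping."""
        flags = set(self.report.flags)
        if self.report.ibi_series.size:
            return "ok"
        if "breath_hold" in flags and "reconstruction_refused" not in flags:
            return "breath_hold"
        return "refused"


def run_pipeline(cube: RadarCube, config: PipelineConfig | None = None,
                 keep_intermediates: bool = False) -> PipelineResult:
    """Run the full chain on a raw radar cube."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    disp = cube_to_displacement(cube, config.torso_bins)
    t1 = time.perf_counter()
    log.info("range processing: %d frames x %d bins in %.2f s",
             disp.traces.shape[1], disp.traces.shape[0], t1 - t0)
    result = process_displacements(disp, config, keep_intermediates)
    if keep_intermediates:
        result.displacements = disp
    result.stage_seconds["range_processing"] = t1 - t0
    return result


def _screen_beats(valley_times: np.ndarray, spike_union: np.ndarray,
                  prf: float, margin_s: float = 0.4,
                  edge_s: float = 2.0) -> np.ndarray:
    """Drop beats that cannot be trusted.

    A valley within ``margin_s`` of a compensated movement spike rides on a
    reconstructed artifact; one within ``edge_s`` of the recording
    boundaries sits in the transient of the zero-phase filters and the VMD
    mirror extension.  Both are removed before IBI work -- the surrounding
    intervals become implausibly long and are screened by the HRV artifact
    rule, rather than polluting the series with mistimed beats.
    """
    n = spike_union.size
    duration = n / prf
    keep = []
    for t in valley_times:
        if t < edge_s or t > duration - edge_s:
            continue
        i0 = max(0, int((t - margin_s) * prf))
        i1 = min(n - 1, int((t + margin_s) * prf))
        if spike_union[i0:i1 + 1].any():
            continue
        keep.append(t)
    return np.asarray(keep)


def process_displacements(disp: BinDisplacementSet,
                          config: PipelineConfig | None = None,
                          keep_intermediates: bool = False) -> PipelineResult:
    """Run the chain from per-bin displacement traces onward."""
    config = config or PipelineConfig()
    prf = disp.prf
    report = VitalsReport()
    result = PipelineResult(report)
    flags = set()
    t_start = time.perf_counter()

    compensated = np.empty_like(disp.traces)
    spike_union = np.zeros(disp.traces.shape[1], dtype=bool)
    for i, trace in enumerate(disp.traces):
        compensated[i], mask = compensate_movement(trace, config.motion)
        spike_union |= mask
    if spike_union.any():
        flags.add("movement_compensated")
    if spike_union.mean() > 0.2:
        flags.add("movement_heavy")
    if keep_intermediates:
        result.compensated = compensated
    t_comp = time.perf_counter()

    # breathing per bin; all bins see the same torso so estimates agree
    per_bin_resp = []
    window = min(60.0, compensated.shape[1] / prf)
    for trace in compensated:
        try:
            per_bin_resp.append(
                estimate_br(trace, prf, window=max(20.0, window),
                            band=config.breathing_band,
                            breath_hold_floor_mm=config.breath_hold_floor_mm))
        except BreathHold:
            per_bin_resp.append(None)
    valid_resp = [r for r in per_bin_resp if r is not None]
    if valid_resp:
        report.per_bin_br = [r.br for r in valid_resp]
        report.br = float(np.median(report.per_bin_br))
    else:
        flags.add("breath_hold")
    t_resp = time.perf_counter()

    cardiac_band = (config.breath_hold_cardiac_band
                    if not valid_resp else config.cardiac_band)
    per_bin_valleys, per_bin_hr, waveforms = [], [], []
    fundamental, orders = None, []
    for i, trace in enumerate(compensated):
        resp = per_bin_resp[i]
        try:
            band_trace = bandpass_cardiac(trace, prf, cardiac_band)
            if np.sqrt(np.mean(band_trace**2)) < config.cardiac_floor_mm:
                flags.add("insufficient_beats")
                continue
            if config.use_vmd:
                imfs = vmd_decompose(band_trace, config.vmd, fs=prf,
                                     f_band=cardiac_band)
                plan = select_harmonics(imfs, resp, config)
                wave = reconstruct(plan, imfs)
                waveform, f0 = wave.trace, wave.fundamental
                if fundamental is None:
                    fundamental, orders = f0, wave.harmonic_orders_used
                valleys = detect_valleys(waveform, prf, expected_rate_hz=f0)
            else:
                waveform = band_trace
                valleys = detect_valleys(waveform, prf)
        except NoCardiacFound:
            flags.add("no_cardiac_found")
            continue
        except ReconstructionRefused:
            flags.add("reconstruction_refused")
            continue
        except InsufficientBeats:
            flags.add("insufficient_beats")
            continue
        hrv = None
        if valleys.size >= 4:
            try:
                hrv = compute_hrv(valleys)
            except InsufficientBeats:
                hrv = None
        per_bin_valleys.append(valleys)
        per_bin_hr.append(hrv.hr if hrv else 60.0 / np.diff(valleys).mean())
        waveforms.append(waveform)
    t_cardiac = time.perf_counter()

    report.fundamental_hz = fundamental
    report.harmonic_orders = orders
    if keep_intermediates:
        result.per_bin_waveforms = waveforms
    result.per_bin_valleys = per_bin_valleys
    report.per_bin_hr = list(per_bin_hr)

    if per_bin_valleys:
        fused, surviving, ref = fuse_bins(
            per_bin_valleys, per_bin_hr, config.motion,
            config.valley_match_window_s)
        report.surviving_bins = [int(b) for b in surviving]
        if len(surviving) == 1 and len(per_bin_valleys) >= 3:
            flags.add("single_bin_fallback")
        fused = _screen_beats(fused, spike_union, prf)
        report.valley_times = fused
        try:
            hrv = compute_hrv(fused)
            report.hr = hrv.hr
            report.ibi_series = hrv.ibi_series
            report.rmssd = hrv.rmssd
            report.sdrr = hrv.sdrr
            report.pnn50 = hrv.pnn50
        except InsufficientBeats:
            flags.add("insufficient_beats")
        report.morphology = classify_morphology(
            waveforms[ref] if ref < len(waveforms) else waveforms[0],
            prf, per_bin_valleys[ref])
    else:
        report.morphology = "indeterminate"
        if not flags:
            flags.add("insufficient_beats")

    report.flags = sorted(flags)
    result.stage_seconds.update({
        "motion_compensation": t_comp - t_start,
        "respiration": t_resp - t_comp,
        "cardiac": t_cardiac - t_resp,
    })
    log.info("pipeline stages (s): %s", result.stage_seconds)
    return result
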