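"""Cardiac-band isolation and harmonic-selection reconstruction.

After movement compensation and breathing estimation, the 0.8-6 Hz band
holds the cardiac fundamental and its harmonics -- and, during deep
breathing, leaked 2nd-4th breathing harmonics of comparable amplitude.
The reconstruction rule: the strongest VMD mode that is *not* an integer
multiple of the breathing rate is the cardiac fundamental; modes at 2-4x
that fundamental join it unless they too sit on a breathing multiple; at
least two components are required, otherwise reconstruction is refused
rather than reporting a breathing harmonic as a heartbeat.

The lower band edge matters: a 1 Hz edge suppresses a 55 beats/min
fundamental and makes the 2nd harmonic masquerade as HR, so the default
edge is 0.8 Hz (a 0.9 Hz tone passes with under 3 dB loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import NoCardiacFound, ReconstructionRefused
from .respiration import RespirationEstimate, bandpass
from .vmd import IMFSet, dominant_mode

__all__ = ["CardiacWaveform", "HarmonicPlan", "bandpass_cardiac",
           "select_harmonics", "reconstruct"]


@dataclass
class HarmonicPlan:
    """Which modes build the cardiac waveform."""

    fundamental_hz: float
    mode_indices: list[int]          # all member modes, fundamental first
    harmonic_orders: list[int]       # matched orders, ascending
    components: list[list[int]] = None  # member modes per matched order

    def __post_init__(self) -> None:
        if self.components is None:
            self.components = [[m] for m in self.mode_indices]


@dataclass
class CardiacWaveform:
    """Reconstructed cardiac displacement with its harmonic pedigree."""

    trace: np.ndarray                # mm
    fundamental: float               # Hz
    harmonic_orders_used: list[int]
    source_mode_indices: list[int]
    fs: float
    hr_spectral: float = field(init=False)

    def __post_init__(self) -> None:
        self.hr_spectral = 60.0 * self.fundamental


def bandpass_cardiac(trace, prf: float,
                     band: tuple[float, float] = (0.8, 6.0)):
    """Zero-phase cardiac band-pass (default 0.8-6 Hz)."""
    return bandpass(trace, band[0], band[1], prf)


def _breathing_membership(freq: float, breathing: np.ndarray, tol) -> int:
    """Index of the breathing harmonic ``freq`` sits on, or -1."""
    for i, h in enumerate(breathing):
        if abs(freq - h) <= tol(h):
            return i
    return -1


def _group_modes(imfs: IMFSet, breathing: np.ndarray, tol,
                 width: float = 0.3):
    """Cluster adjacent modes into spectral components.

    VMD with a fixed K tends to split a frequency-modulated component (a
    jittering heartbeat spreads its fundamental over a few tenths of a Hz)
    across neighbouring modes; treating modes whose centres lie within
    ``width`` Hz of each other as one component undoes that.  Modes on a
    breathing harmonic never merge with modes off it, so breathing energy
    cannot smuggle itself into a cardiac component.

    Returns ``(groups, centres, powers)`` with groups as lists of mode
    indices, centres power-weighted, powers of the summed group trace.
    """
    order = np.argsort(imfs.center_frequencies)
    groups: list[list[int]] = [[int(order[0])]]
    for k in order[1:]:
        k = int(k)
        prev = groups[-1][-1]
        gap = imfs.center_frequencies[k] - imfs.center_frequencies[prev]
        same_breathing = (
            _breathing_membership(imfs.center_frequencies[k], breathing, tol)
            == _breathing_membership(imfs.center_frequencies[prev], breathing, tol)
        )
        if gap <= width and same_breathing:
            groups[-1].append(k)
        else:
            groups.append([k])
    centres, powers = [], []
    for g in groups:
        p = imfs.powers[g]
        centres.append(float(np.dot(imfs.center_frequencies[g], p) / p.sum()))
        powers.append(float((imfs.modes[g].sum(axis=0) ** 2).mean()))
    return groups, np.asarray(centres), np.asarray(powers)


def select_harmonics(
    imfs: IMFSet,
    resp: RespirationEstimate | None,
    config: PipelineConfig | None = None,
) -> HarmonicPlan:
    """Pick the cardiac fundamental and usable harmonics among the modes.

    Adjacent modes are first grouped into spectral components (see
    :func:`_group_modes`) and components on an integer multiple of the
    breathing rate are excluded.  Among what remains, the cardiac family
    is found by a harmonic-comb search (candidate fundamentals are every
    component frequency and its /2 and /3 subharmonics -- the octave-error
    guard of pitch trackers); the comb that recruits the most component
    power wins, which realises the strongest-non-breathing-component rule
    while staying immune to a dominant 2nd harmonic.  Components within
    tolerance of 2-4x the fundamental join the plan unless they sit on a
    2nd-4th breathing harmonic (breathing exclusion wins).

    ``resp`` may be None (breath-hold: no breathing exclusions).  Raises
    :class:`NoCardiacFound` when every component is a breathing multiple
    and :class:`ReconstructionRefused` when fewer than two usable
    components remain.
    """
    config = config or PipelineConfig()
    tol = config.harmonic_tolerance

    if resp is not None:
        breathing_all = resp.peak_frequency * np.arange(
            1, config.max_harmonic_order + 1)
        # orders 2..4 can reach into the cardiac band and mask harmonics
        breathing_masking = breathing_all[1:]
    else:
        breathing_all = np.empty(0)
        breathing_masking = np.empty(0)

    groups, centres, powers = _group_modes(imfs, breathing_all, tol)
    non_breathing = [
        i for i in range(len(groups))
        if _breathing_membership(centres[i], breathing_all, tol) < 0
    ]
    if not non_breathing:
        raise NoCardiacFound(
            "every candidate mode is an integer multiple of the breathing rate"
        )

    # a component spans the centre frequencies of its member modes; a
    # jittering high harmonic spreads over several tenths of a Hz, so
    # matching tests the span, not just the weighted centre
    spans = [
        (float(imfs.center_frequencies[min(g, key=lambda m: imfs.center_frequencies[m])]),
         float(imfs.center_frequencies[max(g, key=lambda m: imfs.center_frequencies[m])]))
        for g in groups
    ]

    def matches(i: int, target: float) -> bool:
        lo, hi = spans[i]
        return lo - tol(target) <= target <= hi + tol(target)

    def build_plan(f0: float):
        """Match components to orders 1..max of candidate fundamental f0."""
        selected: list[int] = []
        orders: list[int] = []
        for order in range(1, config.max_harmonic_order + 1):
            target = order * f0
            cand = [i for i in non_breathing
                    if i not in selected and matches(i, target)]
            if not cand:
                continue
            best = min(cand, key=lambda i: abs(centres[i] - target))
            # a cardiac harmonic sitting on a breathing multiple is
            # discarded: breathing exclusion wins (the non_breathing filter
            # already enforces this; the masking list can be wider)
            if order > 1 and breathing_masking.size and np.any(
                np.abs(centres[best] - breathing_masking)
                <= [tol(f) for f in breathing_masking]
            ):
                continue
            selected.append(best)
            orders.append(order)
        return selected, orders

    # Harmonic-comb search for the fundamental.  The strongest
    # non-breathing component usually *is* the fundamental, but the
    # two-peak cycle puts almost as much power into the 2nd harmonic
    # (octave ambiguity), and a fundamental dragged onto a nearby
    # breathing harmonic disappears from the candidate list while its
    # 2nd-4th harmonics survive.  Every component frequency and its /2
    # and /3 subharmonics are therefore tried as candidate fundamentals;
    # the comb recruiting the most component power wins, ties preferring
    # a comb whose order-1 line is present, then the lower frequency.
    candidates: list[float] = []
    for i in non_breathing:
        for base in [centres[i]] + [imfs.center_frequencies[m] for m in groups[i]]:
            for divisor in (1, 2, 3):
                f = float(base) / divisor
                if 0.4 <= f <= imfs.fs / 2 and all(
                    abs(f - c) > 0.02 for c in candidates
                ):
                    candidates.append(f)

    best = None
    for cand_f0 in candidates:
        selected, orders = build_plan(cand_f0)
        if len(selected) < 2:
            continue
        # a family holding neither the fundamental nor the 2nd harmonic
        # (both masked by breathing) is not a credible heartbeat
        if not {1, 2} & set(orders):
            continue
        # nor is one assembled from noise-level scraps
        if sum(powers[i] for i in selected) < 0.05 * powers.max():
            continue
        total_power = float(sum(powers[i] for i in selected))
        key = (total_power, 1 in orders, -cand_f0)
        if best is None or key > best[0]:
            best = (key, selected, orders, cand_f0)

    if best is None:
        raise ReconstructionRefused(
            "the cardiac waveform cannot be reconstructed: fewer than two "
            "usable harmonics"
        )
    _, selected, orders, f0 = best
    # report the fundamental as the comb sees it: the order-1 component
    # centre when present, the comb base frequency otherwise
    if 1 in orders:
        f0 = float(centres[selected[orders.index(1)]])
    components = [list(groups[i]) for i in selected]
    mode_indices = [m for g in components for m in g]
    return HarmonicPlan(float(f0), mode_indices, orders, components)


def reconstruct(plan: HarmonicPlan, imfs: IMFSet) -> CardiacWaveform:
    """Sum the planned modes into the cardiac waveform."""
    if len(plan.mode_indices) < 2:
        raise ReconstructionRefused("plan must contain at least two components")
    trace = imfs.modes[plan.mode_indices].sum(axis=0)
    return CardiacWaveform(
        trace=trace,
        fundamental=plan.fundamental_hz,
        harmonic_orders_used=list(plan.harmonic_orders),
        source_mode_indices=list(plan.mode_indices),
        fs=imfs.fs,
    )
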