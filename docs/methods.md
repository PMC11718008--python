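# Methods

## Forward model

### Radar waveform

The simulated sensor is a 60 GHz FMCW radar: sweep start 58 GHz, bandwidth
5 GHz (chirp slope 78.128 MHz/µs, so the sweep time `T = BW/K` ≈ 64 µs
matches the 64 fast-time samples at 1 MHz), 32 chirps per frame, 20 frames/s.
The frame rate is twice the highest vibration frequency carried by the model
(10 Hz). Derived geometry: range resolution `ΔR = c/2BW` = 2.998 cm, maximum
unambiguous range 32·ΔR = 95.9 cm, sweep-centre wavelength `λ = c/60.5 GHz`
= 4.955 mm.

Each chirp is rendered as `cos(2π f_min t_d + 2π K t t_d)` per scatterer with
`t_d = 2(R₀ + d(t))/c`. Two approximations are deliberate:

* sub-millimetre motion enters only through the delay phase — the range walk
  of `d(t)` across one chirp is orders of magnitude below a range bin;
* displacement is constant within a frame (the 32 chirps span ~2 ms of the
  50 ms frame period).

The slow-time phase of a range-FFT peak then tracks motion at the sweep
*centre* frequency: the carrier term contributes `4π f_min/c` per metre and
the intra-chirp beat ramp adds `≈ 2π BW/c`, which is why displacement is
scaled by the centre wavelength, `d = φ·λ/4π`.

Noise enters twice:

* **oscillator phase noise** — an independent random phase per chirp, common
  to all scatterers, default 0.05 rad SD. This makes the single-chirp
  displacement noise floor ≈ λ/4π·0.05 ≈ 20 µm, i.e. the same order as the
  cardiac displacement itself, and is the reason the chain averages the 32
  chirps of a frame (white-noise suppression 10·log10 32 ≈ 15 dB);
* **receiver noise** — white Gaussian samples added to the cube, default
  0.15 of the per-scatterer amplitude, giving ≈ 2 µm per-frame displacement
  noise per bin, independent across bins (this is what multi-bin fusion can
  average away; the common-mode phase noise is not reducible by fusion).

### Torso and physiology

The seated torso is modelled as 6 point scatterers at consecutive range bins
spanning 12–27 cm (adult torsos are wider than 40 cm, so a seat-back radar
fills several 3 cm bins), all moving with the same displacement and carrying
independent reflectivity gains drawn from U(0.8, 1.2).

The displacement is the sum of:

* **breathing** — a sinusoid at the breathing rate (0.1–0.8 Hz band) with
  default amplitude 1 mm plus harmonics 2–4 at relative weights
  0.06/0.03/0.015. The weights are set so the harmonics that reach the
  cardiac band carry 15–60 µm, comparable to the cardiac displacement —
  breathing-harmonic rejection is then a real, not cosmetic, part of the
  problem. Normal-breathing amplitude is a modelling choice (only the
  breath-hold bound, < 0.15 mm, is an established figure);
* **cardiac cycles** — a fixed unit-cycle template, time-scaled per beat by
  a mean-reverting AR(1) interbeat-interval sequence (lag-1 correlation 0.6,
  configurable mean and SD, clipped to 0.3–1.5 s) and scaled to 0.02 mm.
  Two template shapes exist: the typical cycle with two peaks followed by a
  deep valley at cycle phase 0.80, and a three-peak variant. The bump
  geometry was chosen (once, numerically) so that three contracts hold
  simultaneously for peak ratios ~0.6–1.2: the fundamental is the strongest
  harmonic, the advertised peak count survives a reconstruction truncated to
  harmonics ≤ 4 at 20 % prominence, and the valley location shifts by only a
  few ms when the 4th harmonic is dropped from a plan (valleys must be a
  robust fiducial). Ground truth records the valley time of every complete
  cycle, `s_k + 0.80·IBI_k`;
* **movement events** — Hann-shaped pulses (return to baseline) or
  smoothstep DC steps (persistent offset), with magnitudes/durations chosen
  so the per-frame derivative exceeds the compensation threshold; slower or
  smaller motion is, by this chain's definition, not an artifact. Default
  pulses (3–6 mm over 0.6 s) stay within the unwrapper's tracking range
  (< λ/4 per frame).

### What the generator does not emulate

Intermodulation between breathing and cardiac motion (bounded below the
cardiac line by the Bessel-function argument ordering and therefore ignored),
posture changes, per-bin independent physiological motion (all bins share
one displacement, so cross-bin outlier rejection fires less often than on
real data), RF clutter/multipath, antenna patterns and inter-radar
interference. Passing tests therefore demonstrate the chain's correctness
and noise robustness under this model, not performance on human subjects.

## Inverse chain

Stage order: per-chirp DC removal → chirp averaging → fast-time FFT
(rectangular window; isolated point scatterers) → per-bin phase extraction,
`np.unwrap`, λ/4π scaling, initial-offset removal → movement compensation →
breathing estimation → cardiac band → VMD → harmonic selection →
reconstruction → valley detection → fusion → metrics.

**Movement compensation.** First differences above 0.48 mm/sample are
zeroed and the trace re-integrated. The detected mask is dilated ±3 samples:
a real artifact rises and falls *through* the threshold, so its
sub-threshold tails belong to it (without dilation the leftover tails put
tens of µm of broadband energy into the cardiac band, ten times the
heartbeat). Spike-free traces pass through bit-identically. The 0.48
default is an empirical mean+3·SD calibration on clean seated-breathing
steps; `calibrate_threshold`
recomputes mean+3·SD on clean reference traces.

**Breathing.** Welch periodogram (Hann, ≤ 60 s segments, 50 % overlap,
zero-padded) of the 0.1–0.8 Hz band-passed trace with parabolic peak
refinement. Band RMS below 0.15 mm flags a breath-hold (BR undefined; the
cardiac band then defaults to the 0.8–3 Hz preset and no breathing
exclusions apply).

**Filters.** Zero-phase 4th-order Butterworth band-passes
(`sosfiltfilt`): > 40 dB an octave outside either band edge, and the
0.8 Hz lower cardiac edge passes a 0.9 Hz (54 beats/min) fundamental with
< 3 dB loss — a 1 Hz edge provably halves slow heart rates by promoting
the 2nd harmonic.

**VMD.** Canonical ADMM formulation: alternating Wiener-filter updates of
K = 10 analytic mode spectra and power-weighted centre-frequency updates.
Defaults: bandwidth penalty α = 2000 (in the conventional normalised-
frequency scaling; half-power mode half-width ≈ 0.32 Hz at 20 Hz sampling —
wide enough to track 40 ms beat-to-beat jitter, narrow enough to separate
lines ≳ 0.3 Hz apart), dual step τ = 0 (no exact reconstruction, tolerant
to noise), tolerance 1e-7, ≤ 500 sweeps (best iterate returned with a flag
on non-convergence), uniform-grid initialisation over the processed band.
The signal is mirror-extended by half its length per side and trimmed
after. Initial centre frequencies are sorted, so any relabelling of the
initialisation yields identical output. Mode strength is time-domain mean
square; modes are returned sorted by centre frequency.

**Harmonic selection.** Adjacent modes (centres within 0.3 Hz) are grouped
into components first — VMD splits a frequency-modulated heartbeat across
neighbouring modes — with the rule that modes on a breathing multiple never
merge with modes off one. Components within max(0.05 Hz, 3 %) of k·BR
(k = 1–4) are breathing and excluded. The cardiac family is then found by a
harmonic-comb search: every remaining component frequency and its /2 and /3
subharmonics are tried as candidate fundamentals, components matching
orders 1–4 of the comb are recruited (span-based matching, since a
jittering high harmonic spreads over several tenths of a Hz), and the comb
recruiting the most power wins. This realises the strongest-non-breathing-
component rule while surviving its two failure modes: the two-peak cycle
puts almost as much power in the 2nd harmonic as in the fundamental (octave
ambiguity), and a fundamental dragged onto a nearby breathing harmonic
vanishes from the candidate list while its harmonics remain. A family is
rejected if it holds neither order 1 nor order 2, or carries less than 5 %
of the strongest component's power; fewer than two usable components is a
refusal — reporting a breathing harmonic as a heartbeat is worse than
reporting nothing. When a cardiac harmonic and a breathing harmonic claim
the same component, breathing wins.

**Valleys, fusion, metrics.** Valleys are local minima with prominence
≥ 30 % of the waveform's 2nd–98th percentile span, separated by ≥ 0.3 s
(or 60 % of the spectral cycle when the fundamental is known, which
suppresses the shallow inter-peak dip), refined by parabolic interpolation.
Per-bin HR estimates pass one-sigma outlier rejection; surviving bins'
valleys are pooled and grouped within ±250 ms (at most one per bin), and
groups supported by a majority of bins become fused beats at the group
median — a beat hallucinated by one bin never reaches the IBI series.
Fused beats within 0.4 s of a compensated movement spike or 2 s of the
recording edges (filter/mirror transients) are dropped. HRV uses the
standard time-domain definitions (SDRR with ddof = 0); intervals outside
300–1500 ms or deviating > 30 % from the series median are artifacts
(missed beat → double interval, split beat → two half intervals) and are
removed, with successive differences taken only between adjacent surviving
intervals.

**Morphology.** The waveform is FFT-upsampled ×4; valley-to-valley cycles
are resampled to a common length and ensemble-averaged. The ensemble
cycle's peak count (prominence 12 % of its span) sets the label — two peaks
typical, three or more atypical — provided more than half of the individual
cycles reproduce every ensemble peak near its phase (lenient 10 %
prominence, ±6 % cycle window); a typical label is withdrawn when ≥ 30 % of
cycles carry a strong extra peak, so mixed populations come out
indeterminate. Morphology study cohorts use calm, shallow (0.5 mm)
breathing: waveform-shape claims in this field come from calm or
breath-hold segments, where breathing harmonics do not bury the weak first
peak.

## Evaluation conventions

Estimated valleys are matched one-to-one to true valleys (nearest within
±250 ms, closest pairs first); IBI errors compare consecutive matched true
beats, so a constant timing offset is invisible (and reported separately as
the valley offset). HR and HRV errors compare metrics of the full estimated
and true IBI series under the same artifact screen.

The shipped cohort (used by the acceptance script and the heaviest tests)
draws 8 subjects with breathing 9–20 breaths/min, mean IBI 0.65–1.1 s,
40 ms IBI jitter and three movement pulses per 300 s recording. Draws whose
cardiac fundamental lands within 0.18 Hz (0.14 Hz for the weak 4th
harmonic) of a breathing multiple are rejected and redrawn: a decomposition
with ~0.3 Hz mode bandwidth cannot separate closer lines, the chain refuses
such recordings by design, and a metronome protocol cannot hold HR at an
exact multiple of BR either. Problem sizes (300 s, 8 recordings; 120 s for
the 20-recording morphology cohorts) were chosen to give a few hundred
beats per recording while keeping a full study run in minutes on one core.

## Known limitations

* All range bins share one displacement source, so the cross-bin outlier
  stage is exercised mainly by noise and rarely by genuinely corrupted
  bins; its benefit on real data (where bins decorrelate during movement)
  is likely larger than the synthetic margin suggests.
* Common-mode oscillator phase noise sets the timing-jitter floor for the
  fused IBI series; fusion only averages receiver noise.
* Empty range bins (no target) produce phase-noise random walks; the chain
  screens them by the cardiac-band floor (2 µm RMS) and the cross-bin HR
  outlier rule, but bin occupancy is not explicitly detected.
* HR above ~92 beats/min together with BR near 20 breaths/min leaves no
  breathing-multiple-free window and the cohort sampler avoids it;
  tachycardia against fast breathing is outside the validated envelope.
* The morphology classifier needs ≥ 5 complete cycles and assumes the
  reconstruction carries at least the 3rd harmonic when three peaks are
  present.
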