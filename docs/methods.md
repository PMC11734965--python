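# Methods

This note documents the models implemented in `binsim`, the parameters that
matter, the synthetic world the generators emulate, and the design choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scene synthesis

### Head model

A rigid-sphere surrogate replaces measured manikin head-related impulse
responses.

* **ITD** — Woodworth closed form `τ = (a/c)(θ + sin θ)` for the far ear,
  folded about 90° for rear sources; default radius `a = 0.0875 m`,
  `c = 343 m/s`. Realized with unit-energy windowed-sinc fractional delays
  behind a fixed 32-sample latency.
* **Head shadow** — first-order shelving filters above a 1200-Hz corner:
  the contralateral ear is cut (−10 dB at 90°, scaled by |sin θ|) and the
  ipsilateral ear boosted (+6 dB at 90°). The boost exists because real
  heads raise the near-ear level at high frequencies; with a cut-only
  shadow, symmetric maskers could only ever *lose* power at the ears.
  Magnitudes sit inside the range of published manikin interaural level
  differences (≈15 dB at high frequencies for lateral sources).
* **`asymmetry_gain`** — a broadband dB offset on the right ear, emulating
  documented right/left recording asymmetries. Note that it cancels exactly
  in every statistic the SRM model consumes (band SNRs, interaural phase,
  coherence), so it affects rendered stimuli but not predictions.

### Rooms

A 2-D rectangular image-source method (sources and images confined to the
azimuthal plane, mirroring a loudspeaker-ring playback system). Per image:
propagation delay `d/c`, power-law gain `1/d`, reflection coefficient
`β = √(1−α)` per wall contact, atmospheric absorption as a minimum-phase FIR
designed from an ISO-9613-style per-octave dB/m table (cached per 25-m
distance bin), and assignment to the nearest 10° azimuth — ties round toward
the front, matching a quantized loudspeaker ring. Per-azimuth image trains
are convolved with the head model's HRIRs.

The **hall preset** is a calibration, not a reconstruction: no geometry was
published, only RT = 2.4 s and DRR = 4.3 dB at 1.9 m. A 14.8 × 10.8 m plan
with uniform absorption 0.116 and a 3.0-s response meets both targets as
measured by this package's own estimators (RT60 2.34 s, DRR 4.83 dB at
16 kHz). The listener sits on the room's x-midline so that a symmetric head
sees a left/right-symmetric room.

* **RT60** — backward Schroeder integration, line fit over −5…−35 dB (T30)
  extrapolated ×2; an error is raised when the decay range is below 35 dB.
* **DRR** — peak-search onset, 2.5-ms direct window (0.5-ms pre-window),
  `10·log10(direct/tail)`; a tail more than 100 dB below the direct sound is
  numerical noise and reported as the +inf sentinel.

### Source signals

Sentence surrogates are speech-shaped noise (long-term-average speech
spectrum imposed by a 257-tap FIR whose density is corrected for
octave-band integration) modulated at a syllabic ~4 Hz with depth 0.7 and
word-like gaps (250–450 ms bursts, 60–150 ms pauses at −26 dB, 20-ms
ramps). Babble sums six independent sentence streams and renormalizes.
Everything is deterministic given a seed. These surrogates preserve the
spectro-temporal statistics that the SNR definitions, suppressor, compressor
and SRM model care about; they carry no linguistic content, so nothing here
can speak to lexical effects.

## Stimulus protocol

* 54 cells: 2 rooms × 3 SNRs (3/8/20 dB) × 3 spatial configurations
  (colocated 0°/[0°,0°]; front 0°/[+60°,−60°]; side +60°/[0°,−60°]) × 3
  processing settings; 10 repetitions → 540 trials/listener, uniquely
  shuffled per listener; babble segments drawn without replacement from a
  9-segment pool.
* Precursor: time-reversed copy of the sentence + 200-ms gap + sentence; the
  reversed copy matches the target's spectrum and level so its reverberant
  tail masks the target onset realistically. After spatialization the signal
  is pruned at the target's direct-path onset (pruned stimuli cross-correlate
  with the dry target at lag 0).
* SNR: one scalar scales both babbles so that ear-averaged speech power over
  the target span divided by ear-averaged combined-noise power hits the
  nominal value; re-measurement recovers it to well under 0.01 dB. The
  measurement window is the target span, matching the scoring object.
* Levels are relative full scale (source RMS 0.1 ≈ −20 dBFS); no absolute
  SPL calibration is modelled.

## Fitting

* **NAL-R**: `IG(f) = 0.05(H500+H1000+H2000) + 0.31·H(f) + k(f)` with
  k = {−17, −8, +1, −1, −2, −2} dB at the six band centres, clamped ≥ 0.
  With zero loss this leaves +1 dB at 1 kHz — the rule's own output, kept
  as is (the normal-hearing study group uses flat 0-dB gains instead).
* **WDRC parameters**: the genuine NAL-NL2 tables are proprietary; the
  documented stand-in maps `CR = 1 + H/100` clipped to [1, 3], kneepoint
  45 dB, and anchors band gains so a 65-dB input gets exactly the NAL-R
  gain. Attack 5 ms / release 70 ms defaults (syllabic compression).
* **Frequency lowering**: audible edge `e` = highest band frequency with
  threshold ≤ 60 dB HL; `fc = clip(e, 1500, 3000)`; ratio 1 when audible to
  6 kHz, else `(6000 − fc)/(e − fc)` clipped to [1, 3], falling back to 3
  when the edge coincides with the cutoff.
* **Symmetry criterion**: interaural differences < 15 dB everywhere, or a
  single frequency between 15 and 20 dB.

## Hearing-aid chain

Fixed series order per ear (no shared state across ears): analysis →
suppression → WDRC (or static gains) → synthesis → lowering → delay → vent.

* **Filterbank**: bands are differences of linear-phase FIR lowpass
  prototypes with crossovers at geometric means of the centres
  (250…6000 Hz), so the bands sum *exactly* to a delayed impulse;
  ~30-ms default length.
* **Suppressor**: per 8-ms frame and band, `g = max((p − n̂)/p, floor)` with
  `n̂` the long-term power of the whole *mixture* — deliberately the
  no-benefit configuration in which stationary inputs are driven to the
  6/12-dB floor. Frame gains are smoothed by one frame length; a 0-dB
  setting is an exact identity.
* **WDRC**: 1-ms-hop power envelope with attack/release one-pole smoothing
  (initialized at the first frame), static gain `G0` below the kneepoint
  and slope `1/CR` above, on a scale where full-scale RMS reads 100 dB.
* **Frequency lowering**: complementary linear-phase split at `fc`; the high
  branch is modelled per 16-ms Hann frame (half overlap) as up to 12
  spectral peaks (parabolic interpolation) re-synthesized at
  `fc + (f − fc)/cr` with phase continuity across frames; `cr = 1` bypasses
  exactly.
* **Vent**: 2nd-order Butterworth highpass (aid output) + lowpass (undelayed
  ear-canal leak) at 350 Hz. The pair is power-complementary
  (|HP|² + |LP|² = 1); a coherent sum of *identical* branch inputs has a
  notch at the crossover — inherent to even-order complementary pairs — so
  flatness claims are about the power sum, which is what the chain's two
  physically different inputs experience on average.
* Output delay 10 ms (nearest integer sample); HA receiver response
  deliberately bypassed.

Level semantics: NH linear/mild/strong = suppression 0/6/12 dB only;
HI linear = NAL-R gains; HI mild = 6-dB suppression + WDRC; HI strong =
12-dB suppression + WDRC + lowering.

## SRM predictor

30 ERB-spaced gammatone channels (80–8000 Hz, capped at 0.45·fs), 24-ms
frames with half overlap. Inputs are calibrated to 0-dB broadband SNR per
condition. BE: cell-wise better-ear SNR, ceiled at +20 dB and floored at
−30 dB (bounds keep silent gaps from dominating), frame-averaged,
SII-band-importance weighted (ANSI-style one-third-octave table interpolated
on log-frequency). BU: per-band interaural target/masker phases and masker
coherence from analytic-signal cross-products, then the EC BMLD with jitter
constants σ_ε = 0.25, σ_δ = 105 µs, floored at 0 dB per band (no binaural
penalty). Releases are condition-minus-reference; all-cues = BE + BU by
construction. Target preparation discards the first 45 ms of each sentence,
truncates to the shortest, and averages.

## Synthetic listeners

Logistic psychometric function `p = 1/(1 + exp(−slope·(SNR − SRT)))`,
keyword count binomial(5, p), sentence correct iff all five keywords are
(the conversion rule is configuration, not data). Group SRTs: NH 0 dB,
HI 6 dB, 1.5-dB individual spread, slope 0.5/dB (~12.5 %-points/dB at
midpoint) — values chosen to reproduce the qualitative group ordering and
SNR monotonicity, not any printed percentage. Analysis mirrors the study's
reporting: repetition-averaging per subject before condition means, Cohen's
d on subject means, Bonferroni-adjusted pairwise Welch t-tests. Mixed-model
(LMER) inference is intentionally out of scope.

## Pipeline

`pipeline.run_stage(stage, RunConfig)` for stages scenes → stimuli →
process → predict → listeners → report; each stage writes WAV/CSV/JSON
artifacts plus a manifest (seeds, parameters, SHA-256 hashes) and refuses to
run without its upstream manifest. Identical configurations produce
byte-identical outputs.

## What a green test does and does not establish

The generators emulate the *statistics* the processing chain and model react
to: speech-shaped spectra, syllabic modulation, babble decorrelation,
room-acoustic targets, audiogram-driven prescriptions, binomial scoring.
Green tests therefore establish that the machinery reproduces the printed
design quantities, the calibrated acoustics, the measured chain parameters
and the qualitative spatial-release pattern. They do not establish human
intelligibility percentages (no linguistic content, no real HRTFs, no
listener variability beyond a logistic model).

## Known limitations

* The front-configuration anomaly (front ≈ or below colocated) is **not**
  reproduced: with a left/right-symmetric head the frame-wise better-ear
  statistic is positively biased for symmetric maskers, and the documented
  cause of the anomaly in the original data is manikin-specific HRTF
  asymmetry (a low-frequency masker level rise at both ears) that a
  parametric sphere deliberately lacks. The corresponding acceptance test
  is left failing rather than re-tuned.
* 2-D acoustics only: no elevation, floor/ceiling reflections, or head
  movement.
* The NAL-NL2 and lowering fits are documented simplifications, not the
  proprietary procedures.
* The Wiener suppressor is one member of its family (mixture-based long-term
  noise estimate); variants with faster noise tracking behave differently.
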