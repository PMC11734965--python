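# binsim

Simulation machinery for studying **binaural speech intelligibility in rooms
with hearing aids**: virtual-room binaural scene synthesis, a bilateral
hearing-aid simulator, a better-ear / binaural-unmasking predictor of spatial
release from masking (SRM), and synthetic listeners that stand in for human
behavioral data.

It is aimed at hearing scientists and hearing-aid DSP engineers who want a
fully seeded, self-contained version of a classic headphone experiment: speech
and two six-talker babbles placed at loudspeaker-ring azimuths in an anechoic
space or a concert hall (RT = 2.4 s), mixed at SNRs of 3/8/20 dB, processed by
linear amplification, wide dynamic-range compression (WDRC), Wiener-filter
noise suppression, and frequency lowering, and finally scored by listeners
with logistic psychometric functions.

## The models at the core

**Scenes.** Head-related responses use a spherical-head model: Woodworth ITD
`τ = (a/c)(θ + sin θ)` plus first-order head-shadow shelving (contralateral
cut, ipsilateral boost). Rooms are simulated with a 2-D image-source method;
each virtual image is quantized to the nearest 10° azimuth, attenuated by
`1/d`, wall reflections, and per-octave atmospheric absorption. The packaged
hall preset is calibrated to RT60 = 2.4 s and DRR = 4.3 dB at 1.9 m.

**Hearing aid.** Per ear: six-band linear-phase FIR analysis (250–6000 Hz) →
Wiener suppression with a stimulus-long noise estimate (floors 6/12 dB) →
WDRC (static slope `1/CR` above a 45-dB kneepoint, attack 5 ms / release
70 ms) → sinusoidal-model frequency lowering `f′ = fc + (f − fc)/cr` →
10-ms output delay → 350-Hz Butterworth vent pair mixing with the undelayed
ear-canal leak.

**SRM predictor.** Gammatone band decomposition (30 ERB-spaced channels);
better-ear glimpsing takes the per-band/frame max of the two ears' SNR with
SII band-importance weighting; binaural unmasking applies the
equalization-cancellation BMLD
`max(0, 10·log10((k − cos(φ_t − φ_m))/(k − ρ)))` with
`k = (1 + σ_ε²)·exp((2π f_c)² σ_δ²)`, σ_ε = 0.25, σ_δ = 105 µs. The total
release is BE + BU relative to the anechoic colocated reference.

## Worked example

```bash
python examples/01_room_acoustics.py
```

prints (numbers from an actual run):

```
hall   RT60 = 2.34 s   (calibration target 2.4 s)
hall   DRR  = 4.83 dB  (calibration target 4.3 dB)
anech  DRR  = inf  (direct path only: +inf sentinel)
head   ITD(60 deg) = 0.488 ms  (Woodworth closed form)
```

i.e. the simulated hall lands on its reverberation-time and
direct-to-reverberant calibration targets, and the head model reproduces the
closed-form interaural time difference. `examples/04_srm_prediction.py 6 4`
(scaled down from the 50-masker protocol) prints the SRM table:

```
    room    config  be_only  bu_only  all_cues
anechoic colocated     0.00     0.00      0.00
anechoic     front     0.26     1.64      1.90
anechoic      side     4.84     1.45      6.29
    hall colocated    -0.82     0.00     -0.82
    hall     front    -0.39     1.51      1.12
    hall      side     1.41     1.31      2.72
```

The side configuration gains ~5–6 dB from better-ear glimpsing plus binaural
unmasking, and reverberation shrinks both components — the qualitative
pattern expected for spatially separated speech and babble. Other examples
cover stimulus construction (`02`), the hearing-aid chain (`03`), and
synthetic-listener statistics (`05`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package from scratch and records: the SRM of the reference
condition against itself, the hall preset's measured RT60 and DRR, the
measured suppressor attenuation at the mild and strong settings, the
hearing-aid output delay, and the vent half-power frequency — every value
computed by simulation and measurement at run time, never echoed from
configuration.
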