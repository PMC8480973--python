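# delaystand

Desk-scale simulation and analysis toolkit for standing balance under imposed
sensorimotor delays. The package provides:

- **plant** — a linearized inverted-pendulum balance plant (exact zero-order-hold
  integration), a torque delay line, virtual angular limits (6° anterior / 3°
  posterior) with a supportive-torque ramp and damping, and a 6-point linear
  least-squares forward predictor.
- **controller** — a delayed proportional–derivative stand-in for the human
  balance controller (intrinsic 120 ms sensing delay + 20 ms motor delay +
  imposed delay), with seeded torque noise, closed-loop simulation, stability
  margin search, and grid-based gain retuning.
- **signals** — synthetic data hub: band-limited (0–25 Hz) stochastic vestibular
  stimuli with exact RMS, EMG envelopes carrying a biphasic (~60/100 ms)
  vestibular coupling with a schedulable gain, lapse-mixture button-press
  behavior, and full session designs for every experiment.
- **sway** — 2 s windowed sway-velocity variance with in-limit window
  extraction, percent time within limits, centered sliding-window variance,
  pre-detection peak variance, and exponential curve fitting
  `f(x) = a·exp(−x/b) + c` with 63.2%/95% landmarks.
- **fourier** — segment-averaged (2048-sample, disjoint) stimulus–EMG
  coherence, gain, and cross-covariance with analytic and bootstrap confidence
  limits, biphasic peak extraction with zeroing rules, and participant pooling.
- **wavelet** — a 40-wavelet complex Morlet bank (0.5–25 Hz linear, 3–12
  geometric cycles), transition-averaged time-frequency coherence/gain maps
  with edge trimming, band means, and exponential attenuation fits.
- **perception** — button-press classification against delay periods
  (detected / missed / excluded), detection tables, and Bayesian grid fitting
  of the lapse-mixture psychometric function with posterior-averaged 70%
  thresholds.
- **interface** — CSV + JSON-sidecar trial I/O, run manifests with content
  digests, structured logging, a CLI, and experiment replication drivers.

## CLI

```sh
delaystand synth --experiment exp1 --seed 1 --out out/           # synthesize trials
delaystand simulate --delay-ms 200 --duration-s 60 --seed 1 --out trial.csv
delaystand sway --in trial.csv --report sway.csv
delaystand vest --trials vest_trial.csv --nfft 2048 --out vest.json
delaystand tfcoh --trials exp3_*.csv --out map.json
delaystand percept --trials percept_*.csv --out percept.json
delaystand replicate --experiment exp2-percept --seed 1 --out report/
```

Trial files are plain CSV (columns `time_s, theta_deg, theta_dot_dps,
torque_nm, delay_ms, evs_ma, emg_au, button`) with a `.csv.json` sidecar
holding the sample rate and metadata, so everything round-trips losslessly as
text.

## Notes on scale

Closed-loop simulations default to reduced sample rates (200–500 Hz) in the
tests and replication drivers; the 2000 Hz real-time rate is available via
`PendulumParams(fs=2000.0)` at proportional cost. The zero-order-hold update
is recomputed exactly for whatever rate is chosen.
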