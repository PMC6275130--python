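# Methods

## Signal model

Chest-wall acceleration is modelled as an additive superposition
`a_T = a_L + a_H + ε`. The respiratory term `a_L` is a sinusoid at the
breathing frequency (optionally up to three harmonics, harmonic *k*
scaled by 1/k²); the cardiac term `a_H` is a train of Gaussian-windowed
cosine wavelets, one per beat; `ε` is white Gaussian sensor noise. The
wavelet is `exp(−t²/2σ²)·cos(2πf_c t)` centred on the beat time, so its
maximum coincides exactly with the event being recovered. Amplitudes are
unit-agnostic ("accel units"): every downstream step is scale-invariant,
so no commitment to g versus m/s² is needed.

Simulator defaults define the reference study conditions: 600 s at
50 samples/s; heart rate 76 beats/min and respiration 20 breaths/min (a
resting adult); respiratory : cardiac amplitude 10 : 1 (the respiratory
excursion is the larger, slower motion; no published ratio exists, so one
representative of chest-band accelerometry was fixed once); wavelet
centre 15 Hz with σ = 0.08 s (compact support well above the band split,
inside the 25 Hz Nyquist limit); cycle-to-cycle period jitter 2 %
(resting heart-rate variability is a few percent); noise SD 0.2 × the
cardiac amplitude (a visibly noisy but workable sensor). Jitter
multiplies each inter-beat period by `1 + u`, `u ~ U(−j, +j)` — bounded
and rate-preserving in expectation. One seeded generator draws the beat
schedule first and the noise second, unconditionally of the amplitudes;
this makes traces bit-reproducible and makes the component decomposition
exactly superpose when noise is zero.

The simulator emulates the *statistical* structure a wearable SCG sensor
sees — band-separated quasi-periodic components at controlled rates with
white noise. It does not emulate motion artefacts, sensor drift,
breathing-modulated beat amplitudes, multi-axis coupling, or real SCG
waveform morphology (systolic complexes); passing recovery tests
therefore demonstrates correctness of the processing chain under the
stated model, not clinical accuracy on human recordings.

## Band separation

Second-order Butterworth filters, high-pass and low-pass, both at
0.5 Hz by default (only one cutoff is part of the published design; the
low-pass order and cutoff default to the same values but are
configurable). Filters are always designed from the physical cutoff in
hertz; `normalized_cutoff` exposes both the sampling-rate convention
(0.5 Hz at 50 Hz → 0.01) and the Nyquist convention (→ 0.02) read-only,
because the two conventions are a recurring source of off-by-2× bugs.

Offline mode applies each filter forward and backward (`filtfilt`):
zero phase lag — peak *timing* drives all rate estimation — at the cost
of squaring the magnitude response. A single-pass causal mode exists for
streaming parity; its group delay is left uncompensated and documented.
The first and last 5 s of a record are flagged as settling transient
(a 0.5 Hz second-order filter needs a few seconds to settle); windows
overlapping the margin are marked invalid rather than deleted.

Numerical note: digital designs use the bilinear transform, whose
frequency warping grows toward Nyquist. At 50 Hz sampling the low-pass
magnitude at 10 × cutoff sits ~6 % below the analog closed form
`1/√(1+(f/f_c)^{2n})`; the filter-oracle tests therefore evaluate the
stopband points at 250 Hz sampling (warping < 0.5 %) and the −3 dB point
at the working 50 Hz rate, where prewarping makes it exact.

## Event detection and rates

Beats and breaths are local maxima that (1) exceed `threshold_k` × a
centred 5 s rolling standard deviation, (2) are separated by a
physiological refractory period — 0.27 s for beats (220 bpm ceiling),
1.0 s for breaths (60 brpm ceiling) — with the taller peak winning
conflicts and the earliest sample winning plateau ties, and (3) survive
an amplitude-consistency pass that drops peaks below 0.6 × the median
detected height, on the grounds that events of one physiological source
share an amplitude scale while isolated low-grade maxima are noise.

Two kind-specific choices matter:

* The cardiac band is preconditioned with a zero-phase second-order 2 Hz
  high-pass before detection. A second-order 0.5 Hz split attenuates a
  10× larger respiratory wave at ~0.33 Hz only to ~0.17 of its input —
  bigger than the beat wavelets themselves — so raw beat heights are
  meaningless until that baseline is removed. 2 Hz sits cleanly between
  the leak (≤ 0.5 Hz) and the wavelet energy (~15 Hz) and preserves beat
  timing exactly (zero phase).
* `threshold_k` defaults to 1.5 for beats but 0.5 for breaths: the
  respiratory component is a smooth oscillation whose peak-to-SD ratio
  is only √2 ≈ 1.41, so a 1.5 SD threshold would reject every true
  breath maximum; the cardiac wavelet train is sparse and clears 1.5 SD
  comfortably.

Rates are computed per sliding window (default 60 s length, 10 s hop) as
`60 / median(inter-peak interval within the window)`. The median is
preferred over peak counting because a single missed peak doubles one
interval but barely moves the median. Windows with fewer than two peaks,
rates outside physiological bounds (30–220 bpm, 2–60 brpm), or overlap
with the settling margin are carried with `valid = False`, never
dropped; session summaries (median, mean) use valid windows only and
report the invalid count.

## Healthy measure and classification

The valid-rate distribution is summarised by its length `L` and height
`h`, and the healthy measure is `L / h` per signal kind (the
self-consistent reading of the defining ratios, which as printed cross
their heartbeat/respiration subscripts). "Length" and "height" of a
distribution plot are not formally defined in the source description;
the default operationalisation is the only one consistent with the
integer-looking reference values (17, 10): `L` = max − min of the valid
rates and `h` = the modal count of a histogram with 1-unit bins anchored
at integer multiples of the bin width (anchoring keeps `h` independent
of the sample minimum). A normal-fit variant (`L = 2zσ`, default z = 2;
`h` = expected modal-bin count `n·(Φ(w/2σ) − Φ(−w/2σ))`) is provided,
and every result records which convention produced it. An all-equal
series returns `L = 0` with a degeneracy flag instead of failing.

Classification compares the measure against two increasing borders:
below the lower border → healthy, between → emergency, at or above the
upper → dangerous; a value exactly on a border goes to the more severe
class (conservative for a screening statistic). The published material
gives per-class example measures (heartbeat 1.7 / 5.56 / 9.88;
respiration 1.54 / 1.9 / 2.3) but no numeric borders, so the defaults
are the midpoints between adjacent class values — heartbeat (3.63,
7.72), respiration (1.72, 2.10) — fully configurable and carrying no
claim of clinical validity.

## Agreement

Bland–Altman on `d = test − reference`: mean error, sample SD (n−1
divisor, the standard choice), limits mean ± 1.96 SD, RMSE = √mean(d²).
Two identities hold exactly by construction and are property-tested:
`loa_upper − loa_lower = 2·1.96·SD` and
`RMSE² = mean² + SD²·(n−1)/n`. Pairing of two rate series matches each
valid test window to the nearest reference window centre within half a
hop; unmatched windows are excluded and counted. The error table labels
its heartbeat and respiration columns explicitly rather than relying on
row order.

## Pipeline and determinism

`run_pipeline` composes the seven stages (band separation → peak
detection → rate estimation → session summary → distribution shape →
healthy measure → classification, plus agreement when a reference is
given) into one JSON-serialisable report containing the resolved
configuration. Reports embed no timestamps and are rendered with sorted
keys, so identical trace + configuration gives byte-identical JSON.
Stage failures are re-raised with the stage name attached. All
randomness in a run descends from the single simulator/config seed.

## Problem sizes in the test suite

Accuracy tests use 300 s sessions (25 windows, ≥ 23 valid) on the rate
grid HR ∈ {50, 76, 100, 150} × RR ∈ {5, 12, 20, 30}; 300 s gives the
same window statistics as longer sessions while keeping the whole suite
fast. Beat-timing recovery uses a 60 s jitter-free session; spectral and
filter checks use 60–400 s single-tone traces.

## Known limitations

* At 50 Hz sampling an inter-beat interval is quantised to 20 ms, so a
  perfectly recovered 76 bpm session reads 76.92 or 75.00 bpm
  (neighbouring representable medians) — within the ±2 bpm recovery
  band, but visible in reports.
* The 0.5 Hz second-order band split leaves respiratory leakage in the
  cardiac band by design fidelity; detection compensates (2 Hz
  conditioning), but component waveforms returned by `separate_bands`
  retain the leak.
* Respiration at exactly 30 brpm coincides with the 0.5 Hz split: the
  low-pass passes it at half amplitude (still detected reliably); rates
  above that are out of the model's separable regime and rejected at
  simulation time.
* Class borders and the healthy measure carry no clinical validation;
  they summarise distribution shape under this package's conventions.
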