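# Methods

## Pipeline

An interictal multichannel iEEG recording (microvolts, one sampling rate,
optional per-channel SOZ/non-SOZ labels) is cut per channel into
non-overlapping 20-s windows starting at t = 0; a trailing remainder shorter
than 20 s is discarded, never padded, so a 120-minute recording yields
exactly 360 segments per channel. Windows are half-open `[t0, t0+20)`,
indexed by `(channel_id, t0)`, and inherit the channel label.

Each segment is reduced to features along one of two routes:

* **Filter bank + entropies.** The segment is band-passed through the
  physiological bands (Delta 0.5–4, Theta 4–8, Alpha 8–13, Beta 13–30,
  Gamma 30–80, Ripple 80–250, Fast Ripple 250–600 Hz) with a 4th-order
  Butterworth applied forward and backward (`sosfiltfilt`), i.e. zero phase
  and effective order 8. Eight entropy measures are computed per band,
  giving an 8 × B matrix that is flattened entropy-major (8 × 7 = 56
  features at 2 kHz, 8 × 6 = 48 at 512 Hz where Fast Ripple is
  unrepresentable).
* **STFT.** A one-sided Hann-window STFT with a 1-s window and 80 % overlap
  (96 frames for a 20-s segment, frequencies up to fs/2), stored as dB
  magnitude; for the CNN the frequency axis is resampled onto a log grid
  and the image bilinearly resized to 64 × 64 with per-image min-max
  scaling. The 8 × B entropy matrix can likewise be min-max scaled into a
  small image.

Classifiers: an RBF SVM (C = 1, gamma = "scale") and two compact networks —
a fully connected net (input 48/56, hidden 32/32, 2-logit softmax output)
and a CNN (3 × 3 convolution, 32 filters, 2 × 2 max pooling, 128-unit
hidden layer, 2-logit softmax) — trained with Adam (lr 1e-3), batch 64,
cross-entropy. SVM and FCNN features are z-scored with statistics fit on
the training rows only. Per-epoch test accuracy is recorded and summarized
as mean ± SD over the last 10 epochs, so the epoch count must be ≥ 20
(default 100 in the estimators; the test protocols use 40–80, which the
traces show is ample for these input sizes). The networks are implemented
as a small seeded numpy engine (`_nn.py`: dense / 3×3-conv / 2×2-pool
layers, softmax and single-logit heads, Adam); training is bit-reproducible
given the seed.

## Band-set rule at low sampling rates

A band whose upper edge exceeds 0.99 × Nyquist is dropped entirely — its
content cannot exist at that rate, and a truncated stub would measure a
different quantity. An explicit *data band limit* (recordings already
low-pass filtered upstream, e.g. to 150 Hz) instead truncates: bands
starting at or above the limit are dropped and the top remaining band is
cut to the limit (Ripple 80–250 becomes 80–150). Hence 7 bands at 2 kHz,
6 at 512 Hz, and 6 with Ripple 80–150 for 512 Hz data band-limited to
150 Hz.

## Entropy estimators

All logarithms are natural. Histogram measures (Shannon, Rényi α = 2,
Tsallis/generalized q = 2) use 128 equal-width bins over [min, max] of the
band signal; a constant signal occupies a single bin and scores 0. Phase
entropy comes in two variants built on the analytic (Hilbert) signal: the
entropy of the instantaneous-phase histogram over (−π, π], and the entropy
of the successive phase-difference histogram (a pure tone has a constant
increment and scores ≈ 0; broadband noise spreads the increments). The
published sources for the feature set do not pin down which phase-entropy
construction was intended, so the Hilbert-phase pair is used behind a
two-variant interface.

Approximate entropy follows Pincus (self-matches included,
Φ_m − Φ_{m+1}); sample entropy follows Richman–Moorman (−ln(A/B), pairs
over the first N−m templates, self-matches excluded); both use Chebyshev
distance with tolerance r = 0.2 × SD of the band signal and m = 2.
When A or B is zero, sample entropy saturates; the resolution bound
ln((N−m)²) is returned instead of +∞ so downstream feature vectors stay
finite. Permutation entropy is Bandt–Pompe with order 3, delay 1, ties
broken stably by index.

ApEn/SampEn are O(N²); on full 20-s segments (10,240–40,000 samples) that
is the whole pipeline's cost. The extractor therefore decimates the band
signal to at most 1,024 samples (uniform stride) before ApEn/SampEn and
computes both from one shared float32 distance matrix
(`complexity_max_samples`, settable to `None` for exact full-length
computation). The reference implementations `sample_entropy` /
`approximate_entropy` are float64 and match naive enumeration exactly;
the tests hold the fused path to the reference on random vectors.

## PU risk estimator

Labels: y = +1 for SOZ, −1 for non-SOZ. With class-conditional densities
p_p, p_n, prior π_p (assumed known), and the unlabeled marginal
p = π_p·p_p + π_n·p_n, the negative-class term of the supervised risk
π_p·R_p⁺ + π_n·R_n⁻ rewrites as π_n·R_n⁻ = R_u⁻ − π_p·R_p⁻, so

    R̂_pu(g) = π_p·R̂_p⁺(g) + R̂_u⁻(g) − π_p·R̂_p⁻(g)

is an unbiased estimate computable from labeled positives and unlabeled
data alone. `pu_risk` reports the three components and their combination;
the identity holds to machine precision by construction and is property-
tested. The default training loss is the bounded sigmoid loss
ℓ(z, t) = 1/(1 + e^{tz}) (each component then lies in [0, 1]); convex
logistic loss is available.

With a flexible g the plug-in negative part R̂_u⁻ − π_p·R̂_p⁻ can go
negative (overfitting the labeled positives). The non-negative correction
floors it at zero; when a minibatch's negative part is below zero the
update follows the gradient of its negation (a defitting step in the style
of the non-negative PU estimator) while keeping the π_p·R̂_p⁺ term. The
uncorrected estimator remains available (`nn_correction=False`) and is the
one whose unbiasedness is tested. Minibatches draw from the positive and
unlabeled pools proportionally (at least one positive per batch) so all
three risk terms are estimated at every step. g is a three-layer fully
connected net with a single output score; sign(g) is the decision.

When the composition of an experiment is known, the prior of the unlabeled
pool is π_p = (n_pos_total − n_labeled)/n_unlabeled
(`prior_from_composition`); e.g. a balanced 13,500-row fold with 2,142
revealed positives gives π_p ≈ 0.406. Deliberately mis-scaling the prior
(×1.5) measurably degrades PU accuracy, which the acceptance suite checks.

## Evaluation protocols

Shuffled 10-fold cross-validation (fold sizes n/k ± 1) for pooled segment
collections, or a temporal split for continuous recordings: train on all
segments with t0 < 105 min, test on the rest (87.5 % / 12.5 % of a
120-minute recording; 315 vs 45 segments per channel). Partial annotation
reveals round(0.1587 × train size) labeled SOZ segments chosen uniformly
from the positive training rows — 2,142 of a 13,500-row fold, 300 of a
1,890-row temporal train set — and hides all other labels. Accuracy is
segment-level percent correct; net arms are summarized as mean ± SD of the
last 10 epochs. Channel aggregation reports, per channel, the fraction of
its segments predicted SOZ, ranked descending with lexicographic
tie-breaks — decision support, not a hard SOZ call.

`run_experiment` assembles the arms compared throughout: SVM and FCNN on
entropy features, CNN on the entropy image, PU-trained FCNN at the labeled
fraction, and a small-supervised FCNN trained on the same number of rows
(half per class).

## Synthetic data: what it emulates, what it does not

Background is Gaussian noise spectrally shaped to a 1/f^β power spectrum
(β = 2 by default, log-log PSD slope verified within ±0.3), rescaled to a
20 µV SD, plus narrowband theta/alpha sinusoids with random frequency and
phase per channel. Transients follow the standard clinical morphology
classes; the spike is a difference of Gaussians (narrow positive minus
broad negative lobe — an analytic "pointed peak" parameterized purely by
duration), slow waves are half-sines, complexes concatenate components,
and HFO bursts are Hann-windowed sinusoids with carrier in 80–250 Hz.
Durations are validated against the clinical ranges (spike 20–<70 ms,
sharp wave 70–200 ms, slow wave > 1/8 s). Events are placed at uniform
random onsets with same-channel overlap rejection, counts Poisson(rate ×
duration); the event log records every insertion exactly, and every
logged event is verifiable in the signal by cross-correlation at the
logged onset (±1 sample).

Default study conditions: 512 Hz, 3 SOZ + 3 non-SOZ channels, 10 minutes,
SOZ event rate 6/min versus 2/min on non-SOZ channels (propagated or
incidental discharges), 80 µV events over the 20 µV background. These
rates were chosen so the classes genuinely overlap: a 20-s SOZ window is
event-free with probability e^{−2} ≈ 13.5 %, while about half of non-SOZ
windows contain an event, so segment-level accuracy is bounded away from
100 % in the regime where labeled-data volume matters — the regime this
method is for. Under these conditions the three training arms order as
expected (fully supervised ≥ PU ≥ small-supervised) in 9–10 of 10
replicates at the test scale.

Limitations of the generator, hence of what passing tests show: morphology
is stylized (no field spread between channels, no artifacts, no state
changes such as sleep cycles); each channel's background oscillators have
a fixed random frequency, giving channels a spectral fingerprint a
classifier can partially exploit — consistent with the patient- and
recording-specific setting of the method (no cross-recording transfer is
claimed anywhere), but it means synthetic accuracies are pipeline checks,
not estimates of clinical performance.

## Numerical choices and scales

* Filters: SOS form, `sosfiltfilt` default reflective padding; band upper
  edges capped at 0.99 × Nyquist.
* STFT: Hann window, dB via 20·log10(|X| + 1e−12); frames fully inside the
  segment (floor((T − w)/hop) + 1, no edge padding); total spectrogram
  energy matches windowed-frame energy (Parseval, tested within 5 %).
* Feature store: CSV with a header of feature names plus
  `channel_id, t0, label`; read back with round-trip float parsing so the
  store is lossless.
* Network initialization: Glorot uniform from a seeded generator; all
  shuffling from the same seed chain; two runs with equal seed and data
  produce identical epoch traces.
* Test/acceptance scale: the shared benchmark is one 8-channel × 30-minute
  generator-default recording (720 segments, extracted once per session);
  simulation checks use 10 replicate seeds, 40–80 epochs, and recordings
  of 8–30 minutes — sizes at which every targeted effect is stable while
  the whole suite runs in minutes on one CPU.

## Interfaces

EDF/EDF+ is read through mne (with a structural pre-check that all
channels share one sampling rate); delimited csv matrices (header row of
channel ids, rate supplied by flag) are read and written natively. EDF
writing is not offered. The CLI (`sozpu simulate / extract / train /
evaluate / report`) is a thin layer over the library with all randomness
seeded from the command line.
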