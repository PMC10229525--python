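# sozpu

Classification of seizure-onset-zone (SOZ) versus non-SOZ intracranial EEG
(iEEG), for researchers building decision-support tools around epilepsy
surgery work-up. Interictal recordings are cut into 20-s segments, each
segment is reduced to interpretable features — either eight entropy measures
computed in the physiological frequency bands (Delta 0.5–4, Theta 4–8,
Alpha 8–13, Beta 13–30, Gamma 30–80, Ripple 80–250, Fast Ripple 250–600 Hz),
or an STFT spectrogram image — and a compact classifier (RBF-SVM, a
32/32-unit fully connected net, or a small CNN) labels each segment SOZ or
non-SOZ. Segment predictions are aggregated per channel into a ranked report
of probable SOZ channels.

Because expert annotation of iEEG is the bottleneck, the package also
implements **positive-unlabeled (PU) training**: given only a small set of
labeled SOZ segments and a large unlabeled pool with known class prior
π_p = p(y = +1), the supervised risk

&nbsp;&nbsp;&nbsp;&nbsp;R(g) = π_p·R_p⁺(g) + π_n·R_n⁻(g)

is estimated without any labeled negatives through the identity
π_n·p_n = p − π_p·p_p, giving the unbiased PU risk

&nbsp;&nbsp;&nbsp;&nbsp;R̂_pu(g) = π_p·R̂_p⁺(g) + R̂_u⁻(g) − π_p·R̂_p⁻(g),

where R̂_p⁺/R̂_p⁻ are the mean losses of the labeled positives scored toward
+1/−1 and R̂_u⁻ the mean loss of the unlabeled pool scored toward −1. A
non-negative correction (flooring the estimated negative-class part at zero)
keeps flexible networks from driving the estimate below zero. A three-layer
network minimizes this risk by minibatch Adam with a bounded sigmoid loss.

A synthetic iEEG generator (colored 1/f^β background plus clinically
defined interictal transients: spikes 20–<70 ms, sharp waves 70–200 ms,
spike-and-slow-wave and polyspike complexes, ripple-band HFO bursts, at a
higher rate on SOZ channels) makes the full pipeline testable end to end
without any clinical data.

## Worked example

```python
import numpy as np
import sozpu
from sklearn.model_selection import train_test_split
from sozpu.classifiers import FCNNClassifier
from sozpu.pu import PUClassifier, prior_from_composition
from sozpu.evaluation import select_labeled_positives, last_epochs_summary

cfg = sozpu.SynthConfig(n_soz=3, n_nonsoz=3, duration_s=1200.0, seed=42)
rec, log = sozpu.generate_recording(cfg)
segments = sozpu.segment_recording(rec)
ext = sozpu.EntropyFeatureExtractor().fit(segments)
X = ext.transform(segments)
y = np.array([s.label for s in segments], dtype=object)

tr, te = train_test_split(np.arange(len(y)), test_size=0.4,
                          random_state=0, stratify=y)
full = FCNNClassifier(epochs=60, seed=0).fit(X[tr], y[tr], eval_set=(X[te], y[te]))

labeled, unlabeled = select_labeled_positives(y[tr], fraction=0.1587, seed=0)
pi_p = prior_from_composition(int(np.sum(y[tr] == "SOZ")), len(labeled), len(unlabeled))
s = np.zeros(len(tr), dtype=int); s[labeled] = 1
pu = PUClassifier(pi_p=pi_p, epochs=60, seed=0).fit(X[tr], s, eval_set=(X[te], y[te]))
```

Output:

```
recording: 6 channels x 1200 s @ 512 Hz, 465 transients
segments: 360 x 20 s
entropy features: (360, 48) (6 bands x 8 entropies)
fully supervised FCNN: 100.00 +/- 0.00 % (last 10 epochs)
PU setting: 34 labeled SOZ of 216 training rows, pi_p = 0.407
PU-trained FCNN:       90.69 +/- 1.14 % (last 10 epochs)
```

At 512 Hz the Fast Ripple band is unavailable, so each segment carries
8 entropies × 6 bands = 48 features. With every training label the FCNN
separates this synthetic recording perfectly; revealing only 15.87 % of the
training rows as labeled SOZ (34 segments) and training on the PU risk with
the composition-exact prior still reaches ≈91 % — the gap to fully
supervised training is the price of the missing annotations, and it is far
smaller than what the same 34 labels buy in ordinary supervised training.

There is also a CLI mirroring the library:

```bash
sozpu simulate --out rec.csv --events-out events.csv --seed 3 --duration-s 600
sozpu extract --recording rec.csv --features entropy --out features.csv
sozpu train --features features.csv --model fcnn --pu --out predictions.csv
sozpu report --predictions predictions.csv
```

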