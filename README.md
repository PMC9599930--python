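# vmdforest

Automatic epileptic-seizure detection from EEG recordings.  The package
implements a complete detection pipeline for clinical-style long-term EEG:

1. **Segmentation** — recordings are cut into non-overlapping 4-s epochs.
2. **Variational mode decomposition (VMD)** — each epoch's signal is
   decomposed into K = 5 band-limited modes u_k = A_k cos(φ_k) by solving

   min Σ_k ‖∂_t[(δ(t) + j/πt) ∗ u_k(t)] e^{−jω_k t}‖²  s.t.  Σ_k u_k = f

   with ADMM in the frequency domain.  Modes whose Pearson correlation
   with the original signal is ≤ 0.3 are discarded as spurious; the
   surviving (typically three lowest-frequency) modes of all channels form
   the epoch's time–frequency matrix.
3. **Log-Euclidean covariance (LECM) features** — the covariance C of the
   time–frequency matrix is SPD, so it is mapped to a flat space by
   log C = U·Diag(log λ_i)·Uᵀ and half-vectorized column-wise to a
   d(d+1)/2 vector (6 features for one channel, 45 for a three-channel
   focal montage).
4. **Deep forest** — multigrain scanning (windows 5 and 3) turns the
   feature vector into window class probabilities from a random forest and
   a completely-random forest; an adaptively grown cascade of four
   120-tree forests per level refines them, stopping when cross-validated
   accuracy stops improving.
5. **Postprocessing** — the per-epoch probability margin
   P(seizure) − P(nonseizure) is smoothed by a moving-average filter
   y_k = (1/(2M+1)) Σ_{i=−M..M} ŷ_{k+i} (window ≤ 35 epochs), thresholded,
   and each detected run is extended by a collar; the window and threshold
   are tuned per patient on training data by maximizing the epoch G-mean.
6. **Evaluation** — epoch-based sensitivity/specificity/accuracy/G-mean
   and event-based sensitivity plus false detections per hour.

A seeded synthetic-EEG module (1/f background plus ramped 3–5 Hz
harmonic-rich seizure rhythms with exact annotations) makes every stage
testable without any external recording.

## Worked example

`examples/04_detect_seizures.py` trains on a 5-minute synthetic recording
with one 60-s seizure and detects on a disjoint recording:

```
kept modes [0, 1], cascade depth 1, smoothing window 1, threshold -0.90
epoch-based: sensitivity 100.0%, specificity 100.0%, G-mean 100.0%
event-based: 1/1 events detected, 0.00 false detections/h
true seizure (160.0, 220.0), detected (160 s, 220 s)
```

The detector keeps the two modes that carry the seizure rhythm and the
1/f background, grows a single cascade level (the problem is separable),
and recovers the embedded event exactly: every seizure epoch is flagged
(sensitivity) and no background epoch is (specificity), so the single
detected event coincides with the annotated interval.  The other example
scripts demonstrate the VMD oracle behavior (`01`), the feature-space
class separation (`02`) and the deep forest on a toy problem (`03`).

A thin CLI mirrors the library: `seizure synth | train | detect |
evaluate | vmd` (see `seizure --help`); all intermediate artifacts are
plain CSV/JSON.

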