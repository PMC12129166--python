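# bowelgrade

Unsupervised grading of gastrointestinal activity from bowel-sound
(phonoenterogram) recordings.

Abdominal microphones pick up the rumbling and gurgling sounds of
peristalsis. Clinicians would like a number that tracks *how much* activity
a short recording contains, but labelled training data is scarce and event
boundaries are hard to annotate. `bowelgrade` takes a different route: it
never detects individual events. Each fixed 2-second segment is described by
the frame-to-frame **variability of 11 spectral features**, and scored by
its **resemblance to a reference cluster of zero-activity segments** — the
less a segment looks like silence, the more activity it is graded with.

## Method

1. **Ingest** — recordings are band-passed to 100–1000 Hz (zero-phase
   4th-order Butterworth) and cut into 2-s segments; activity annotations
   (interval labels) give each segment a ground-truth activity percentage.
2. **Features** — each segment is framed with a 12.5 ms Hamming window and
   6.25 ms hop; per frame the magnitude spectrum yields centroid, crest,
   decrease, entropy, flatness, kurtosis, roll-off, skewness, slope and
   spread, plus a harmonic ratio from the frame autocorrelation. The
   segment descriptor is the per-feature standard deviation across frames.
3. **Grading** — after joint z-scoring, each test segment x is compared to
   the control cluster (centroid x̄, members mᵢ, i = 1..N) with six
   criteria:
   - Euclidean distance d = ‖x − x̄‖
   - singleton silhouette s = mean over points of (b − a)/max(a, b)
   - cosine similarity c = x·x̄ / (‖x‖‖x̄‖)
   - KNN cluster grade g = (1/k) Σ distances to the k nearest members
   - cluster membership strength CMS = 1 / (mean member distance + ε)
   - Gaussian membership m = exp(−d²/2σ²)

   Similarity-like scores are negated so that **higher always means more
   activity**.
4. **Evaluation** — Spearman's rank correlation ρ (ties averaged) between
   the activity scores and the annotated activity percentages, on the test
   segments above a chosen activity threshold. A greedy forward search can
   select the feature subset maximizing ρ for any criterion.

Because no public study corpus is available, the package ships a seeded
synthetic generator (`bowelgrade.synthetic_data`): white-noise floors with
damped narrow-band bursts inside the analysis band, annotated exactly.

## Worked example

```python
from bowelgrade import synthetic_data as sd

cfg = sd.SynthConfig(seed=1)          # 50 controls, 40 tests, 10-80% activity
results = sd.end_to_end_fixture(cfg)  # ingest -> extract -> grade -> evaluate
for metric, ev in results.items():
    print(f"{metric:10s} rho={ev.rho:+.3f}  |rho|={ev.abs_rho:.3f}  n={ev.n}")
```

prints

```
euclidean  rho=+0.857  |rho|=0.857  n=40
silhouette rho=-0.858  |rho|=0.858  n=40
cosine     rho=+0.429  |rho|=0.429  n=40
knn        rho=+0.877  |rho|=0.877  n=40
cms        rho=+0.860  |rho|=0.860  n=40
gaussian   rho=+0.857  |rho|=0.857  n=40
```

Read: the KNN grade orders the 40 test segments almost exactly by their
true activity (ρ = 0.88). Euclidean and Gaussian agree to the digit — the
Gaussian membership is a monotone transform of the centroid distance, so
their rankings are identical by construction. The silhouette tracks
activity strongly but with the opposite sign under the fixed orientation
(the two-cluster silhouette *improves* as a segment moves away from the
controls); `abs_rho` surfaces such direction instability.

The same workflow is available from the shell:

```sh
bowelgrade simulate --seed 1 --out data/
bowelgrade extract --in data/ --annotations data/annotations.csv --out features.csv
bowelgrade evaluate --features features.csv --metric knn --threshold 30 --out eval.json
bowelgrade select-features --features features.csv --metric knn --threshold 30 --out trace.json
```

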