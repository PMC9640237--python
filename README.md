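# kymovoice

Screening of vocal-fold disorders from high-speed videoendoscopy (HSV)
kymograms, for speech scientists and laryngeal-imaging researchers who want
an end-to-end, fully reproducible analysis chain that runs without any
external recordings.

HSV captures intracycle vocal-fold vibration at thousands of frames per
second. A *kymogram* stacks one fixed cross-section line from every frame
(rows = space, columns = time) and makes the opening and closing of the
glottal gap directly visible. `kymovoice` implements the full chain from
raw frame stacks to a disorder classification:

1. **Synthetic data** (`kymovoice.synthetic`) — a glottal-width simulator
   (rectified cosine with per-cycle jitter/shimmer perturbations and
   HNR-controlled additive noise), a frame renderer (dark glottal slit on
   textured tissue, noisy blue channel, slow vertical camera drift, 8-bit
   quantization), and a labeled voice-parameter table generator. All
   outputs carry their own ground truth.
2. **Preprocessing** (`kymovoice.preprocess`) — temporal segmentation of
   vocalized intervals from inter-frame difference energy, motion
   compensation by integer-shift registration, kymogram extraction.
3. **Features** (`kymovoice.features`) — red and green pixel intensities
   plus an image gradient computed on the red/green mean with an 8-pixel
   step along both axes; the blue channel is excluded as noise.
4. **Peak search** (`kymovoice.peaks`) — a sliding-window detector that
   splits each window into left/center/right sections and marks a peak
   when the center section dominates; peak-to-peak intervals yield jitter
   and shimmer in percent.
5. **Classifier** (`kymovoice.dbn`) — a deep belief network: a
   Gaussian–Bernoulli restricted Boltzmann machine (RBM) with energy

   E(v,h) = Σ_j (v_j − C_j)²/(2σ_j²) − Σ_i c_i h_i − Σ_{j,i} (v_j/σ_j) h_i W_ji

   stacked with Bernoulli–Bernoulli RBMs, pretrained greedily with
   contrastive divergence (ΔW ∝ ⟨v h⟩_data − ⟨v h⟩_reconstruction) and
   fine-tuned with a softmax head by backpropagated cross-entropy.
6. **Hyperparameter tuning** (`kymovoice.ffa`) — the farmland fertility
   algorithm: a population split into k soil regions, the worst region
   refertilized toward a global memory of elite solutions, the others
   perturbed by random peers, memory fusion with a decaying step factor
   ω₁, and greedy replacement under box bounds.
7. **Pipeline** (`kymovoice.pipeline`) — stratified splits, min–max
   scaling, FFA tuning of the validation error, and an evaluation report
   (accuracy, sensitivity/recall, specificity, precision, F-measure, MSE
   of class probabilities, AP/EP rates).

## Worked example

```python
from kymovoice import pipeline

result = pipeline.run_pipeline(
    {
        "seed": 1,
        "n_per_class": 200,
        "normal":     {"f0": [120, 220], "jitter": [0.5, 0.5],
                       "shimmer": [2, 2],  "hnr": [25, 25]},
        "disordered": {"f0": [100, 200], "jitter": [5, 5],
                       "shimmer": [10, 10], "hnr": [10, 10]},
        "tune": True,
        "ffa": {"N": 8, "k": 4, "t": 0.5, "max_iters": 6},
    },
    "artifacts/",
)
print(result["report"])
```

This simulates 400 phonations (200 healthy: jitter 0.5%, shimmer 2%,
HNR 25 dB; 200 disordered: jitter 5%, shimmer 10%, HNR 10 dB), measures
f0/jitter/shimmer/HNR back from each waveform with the package's own peak
analysis, splits 60/20/20, tunes the DBN with the FFA, and evaluates on the
held-out test set. With seed 1 it prints:

```
{'tp': 40, 'fp': 0, 'tn': 40, 'fn': 0, 'accuracy': 1.0, 'sensitivity': 1.0,
 'specificity': 1.0, 'precision': 1.0, 'recall': 1.0, 'f_measure': 1.0,
 'mse': 0.34, 'ap_rate': 100.0, 'ep_rate': 0.0, 'accuracy_pct': 100.0, ...}
```

All 80 test phonations are classified correctly (`accuracy` 1.0); the
mean squared error between the predicted disorder probability and the true
0/1 label is 0.34%, and the AP rate (recall in percent) is 100 with its
complement, the EP rate, at 0. `artifacts/` receives the dataset, the
serialized model, the FFA trace, the report, and a reproducibility
manifest; rerunning with the same config is byte-identical.

The same stages are available from a shell:

```bash
kymovoice simulate --n-per-class 50 --out sim/
kymovoice preprocess --in sim/frames --fps 4000 --row 24 --out pp/
kymovoice features --kymogram pp/kymogram_00.png --pooling per_column --out feat.csv
kymovoice peaks --signal widths.txt --window 25
kymovoice ffa --objective sphere --dim 10 --iters 500 --seed 3 --out trace.csv
kymovoice run --config config.json --out artifacts/
```

## Scope

The package classifies whole phonations as normal vs disordered from
kymogram-derived or acoustic-style features. Photorealistic laryngeal
rendering, audio synthesis, subpixel/deformable registration, and spatial
segmentation networks are out of scope; see `docs/methods.md` for the model
assumptions and limitations.
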