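# eegsync

Adaptive synchronization features for multichannel EEG windows and a
cross-layer fully connected classifier for seizure/non-seizure labelling.

The pipeline has three stages:

1. **Amplitude partitioning** (`eegsync.partitioning`) — each channel
   window's amplitudes are clustered with affinity propagation (implemented
   here, deterministic: no noise injection, fixed tie-breaks); clusters become
   ordered amplitude partitions with centers, radii, and gap-midpoint cut
   points. An equal-probability quantile partitioner is included as the
   conventional baseline.
2. **Pairwise mutual information** (`eegsync.synchrony`) — channel pairs are
   discretized with their (count-equalized) partitions and the empirical MI
   in bits is computed for all pairs, forming a symmetric per-window
   synchronization matrix (diagonal = per-channel self-entropy). Flattened,
   the matrix is the classifier's feature vector (23 channels → 529 features).
3. **Classification** (`eegsync.clfcnn`) — a cross-layer dense network
   (every earlier layer feeds every later layer through its own weight+bias
   edge; per-edge rectification, contributions summed) trained from scratch
   with mini-batch momentum gradient descent, weight decay, inverted input
   dropout, MSE loss, and early stopping on training accuracy. The default
   topology 529 → 80 → 20 → 1 with all six cross edges holds exactly 55,252
   trainable parameters.

Supporting modules: `eegsync.windowing` (non-overlapping window extraction
and class-balanced non-seizure sampling), `eegsync.evaluation`
(sensitivity/specificity/accuracy/precision/G-mean/F-measure and rank-based
ROC AUC), `eegsync.synthetic` (coupled-latent-source surrogate windows with
controllable inter-channel dependence), and `eegsync.readwrite` + a CLI.

## CLI

```bash
# synthetic data: per-window CSVs, labels, and a concatenated recording
# with a seizure-interval sidecar
eegsync simulate --out data/ --channels 8 --samples 512 --windows-per-class 20

# synchronization-matrix features for every (balanced) window
eegsync features --recording data/recording.csv --rate 256 \
    --intervals data/intervals.csv --window 512 --out features.npz

# train with a 64/16/20 split and five-fold cross-validation
eegsync train --features features.npz --out model.json \
    --metrics-out train_metrics.json --seed 7

# apply / score a saved model
eegsync predict --model model.json --features features.npz --out preds.csv
eegsync evaluate --model model.json --features features.npz \
    --out metrics.json --roc-out roc.csv

# sweep window sizes and/or uniform-partition bin counts
eegsync sweep --recording data/recording.csv --rate 256 \
    --intervals data/intervals.csv --out sweep/ --windows 256,512 --bins 2,5,8
```

Only the window size genuinely needs choosing; all other settings default to
the reference configuration. Every run logs its resolved configuration and
seeds.

Notes:

- Affinity propagation is O(N²) per channel window. For long windows the
  `--max-points` flag (or `APConfig.max_points`) clusters evenly spaced order
  statistics and assigns the remaining samples through the learned
  boundaries; the default clusters every point.
- CSV recordings are samples × channels with a channel-name header; EDF
  recordings are read when `pyedflib` or `mne` is importable.

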