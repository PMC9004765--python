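# clicktypes

Detection, unsupervised discovery, and neural-network classification of
odontocete (toothed-whale) echolocation click types in long-term passive
acoustic monitoring data.

Species such as beaked whales, pilot whales, *Kogia* and stenellid dolphins
produce short (30–1200 µs) broadband echolocation clicks whose spectral
peaks, −3 dB bandwidths and inter-click intervals (ICI) are stable enough to
serve as acoustic fingerprints. Given years of single-channel hydrophone
recordings, the workflow implemented here turns raw audio into per-class
time series of acoustic presence:

1. **Detection** — an energy detector finds impulses in the 10–100 kHz band
   (115 dB<sub>pp</sub> re 1 µPa floor, 30–1200 µs duration, events < 100 µs
   apart merged) and stores each click's received level, duration, spectrum
   (400/640-point Hann FFT at fs = 200/320 kHz → 0.5 kHz resolution on a
   common 10–100 kHz grid) and waveform envelope.
2. **Bin features** — detections are grouped into 5-minute bins; each
   cluster in a bin is summarized by its mean min–max-normalized spectrum,
   its ICI histogram (truncated at 0.6 s, 10 ms bins) and its mean envelope.
3. **Two-phase clustering** — phase 1 clusters the clicks of each bin on
   spectral correlation distance with the Chinese Whispers (CW) label-
   propagation algorithm, keeping the partition with the highest average
   normalized mutual information (NMI) over repeated randomized runs;
   phase 2 clusters bin-level mean spectra + envelopes across the dataset
   into click types (≥ 120 dB<sub>pp</sub> clicks only, ≥ 50 clicks per
   cluster, ≥ 25 bins per type, network caps of 10,000 / 20,000 nodes, 1%
   least-connected pruning).
4. **Classification** — a feed-forward network (four 512-node layers, 50%
   dropout, softmax) labels bin clusters from the concatenated
   spectrum ‖ ICI ‖ envelope feature vector (341 values). Training sets are
   balanced to a fixed count per class (5000 at full scale) with a 70/20/10
   train/test/validation split; under-represented classes are topped up by
   noise augmentation confined to the training split.
5. **Evaluation** — per-class accuracy, recall, precision and specificity
   from bin-level confusion matrices, a 125 dB<sub>pp</sub> evaluation
   filter, and relative acoustic presence (percent of recording days with a
   class present, averaged over deployments per site).

Because raw sea recordings of this kind are not shippable, the package
includes a first-class synthetic-scene generator whose ten built-in click
type templates (spectral peaks, bandwidths, modal ICI ± sd, including the
bimodal false-killer-whale ICI) drive every test: clicks are sums of
exponentially damped sinusoids with controlled spectra, click trains follow
truncated-Gaussian ICI models, and scenes add Gaussian background,
ship-band noise and echosounder pings.

## Worked example

```python
import numpy as np
from clicktypes import synth, template
from clicktypes.detection import detect_clicks, detections_to_frame
from clicktypes.clustering import ClusterParams, cluster_bin
from clicktypes.features import assign_bins

scene = synth.SceneConfig(
    fs_hz=200_000, duration_s=30.0,
    trains=(
        synth.TrainSpec(template("cuvier_beaked_whale"), 0.5, 60, (126.0, 140.0)),
        synth.TrainSpec(template("kogia"), 1.0, 60, (126.0, 140.0)),
    ),
    seed=7,
)
audio, truth = synth.render_scene(scene)
detections = detect_clicks(audio, scene.fs_hz, calibration_db=scene.calibration_db)
print(f"injected {len(truth)} clicks, detected {len(detections)}")

frame = detections_to_frame(detections)
params = ClusterParams(min_cluster_size_clicks=30)
rng = np.random.default_rng(0)
for bin_start, idx in sorted(assign_bins(frame).items()):
    for c in cluster_bin(frame.loc[idx], params, rng, bin_start=bin_start):
        print(f"bin {bin_start:6.0f}s cluster {c.cluster_id}: "
              f"{c.member_count} clicks, modal ICI {c.modal_ici_s*1e3:.0f} ms, "
              f"max RL {c.rl_max_dbpp:.1f} dBpp")
```

Output:

```
injected 120 clicks, detected 119
bin      0s cluster 0: 60 clicks, modal ICI 428 ms, max RL 139.7 dBpp
bin      0s cluster 1: 59 clicks, modal ICI 81 ms, max RL 139.7 dBpp
```

The detector recovers 119 of the 120 injected clicks, and phase-1 clustering
cleanly splits the bin into a Cuvier's-beaked-whale cluster (modal ICI
≈ 433 ms) and a *Kogia* cluster (modal ICI ≈ 90 ms).

A command-line interface mirrors the library
(`clicktypes simulate|detect|featurize|cluster|train|classify|evaluate|run-all`);
`clicktypes example-config --out demo.yaml` writes a small end-to-end
configuration.

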