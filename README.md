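# ssfembed

Metric embedding of multichannel live-cell microscopy movies, built around
three ideas:

1. **The cell signaling structure function (SSF).** Kinase translocation
   reporters (KTRs) read out kinase activity by shuttling between nucleus and
   cytoplasm: activation darkens the nucleus relative to the surrounding
   cytoplasm. With channel intensities normalized to [0, 1], the SSF encodes
   the signaling state of a cell as the signed scalar

   H = c − n ∈ [−1, 1]

   (c cytoplasmic, n nuclear intensity). Unlike the conventional cytonuclear
   ratio C/N, H is a *metric* function of (c, n) — a fixed perturbation of the
   intensity pair moves H by a fixed amount anywhere in intensity space —
   which is what makes measurements taken in a downstream embedding valid.
   H is measured without segmentation: the scale-invariant Laplacian-of-
   Gaussian (LoG) response at the cell centroid, at a radius matched to the
   nucleus and calibrated against an ideal dark spheroid, reads off c − n
   directly. The same machinery stores other per-cell functionals, e.g.
   normalized cell velocity, in the same sparse (x, y, time) volumes.

2. **Normalized compression distance (NCD).** Per movie and channel, the SSF
   values at all cell centroids form a sparse 3D volume. After a pooled
   8-bit quantization, the dissimilarity between two movies is

   NCD(x, y) = (Z(xy) − min(Z(x), Z(y))) / max(Z(x), Z(y)),

   with Z the size in bytes of a lossless compression and xy the
   concatenation along time — a practical approximation to the (uncomputable)
   normalized information distance, requiring no model of the expected
   dynamics and no training data. Backends: an external FLIF binary when
   installed, or the built-in LZMA stream backend (the default).

3. **Spectral embedding and the cluster structure function (CSF).** Classical
   multidimensional scaling of the pairwise NCD matrix places each movie as a
   point in a low-dimensional space whose Euclidean geometry approximates the
   NCD; the retained dimension equals the number of experimental classes.
   The CSF scores how meaningfully the embedding represents a labeled
   partition: each point's optimality deficiency is its distance to its own
   cluster centroid, per-cluster means are averaged across clusters, and
   lower is better. Paired conditions are compared with a Wilcoxon
   signed-rank test.

The package also ships the synthetic generators used to validate all of the
above: a single-cell KTR phantom whose shot-noise level encodes a known
activation, three-class constant-velocity SSF corpora, and raw moving-nuclei
movies with exact ground truth.

## Worked example

Recover the activation of a noisy KTR phantom. At 60% activation the phantom
flips 20% of nuclear pixels white and 20% of cytoplasmic pixels black; the
calibrated LoG at the cell centroid still reads the true activation:

```python
from ssfembed.pipeline import ktr_activation_experiment

recovered = ktr_activation_experiment(0.6, n_trials=100, seed=11)
print(f"recovered activation: {recovered:.3f}")
```

```
recovered activation: 0.608
```

i.e. 60.8% recovered against a ground truth of 60%, averaged over 100 noise
draws. Swept over activations 0.0–1.0 the recovery is linear with slope ≈ 1
and intercept ≈ 0.

Run the full embedding pipeline on the synthetic velocity corpus — three
classes of movies whose cells move at mean speeds 1, 3 and 5 px/frame, with a
velocity channel and a control channel holding uniform-random values:

```python
from ssfembed.pipeline import velocity_embedding_experiment

exp = velocity_embedding_experiment(images_per_class=20, seed=7)
for chan in ("velocity", "random"):
    r = exp[chan]["csf"]
    print(f"{chan:8s}  CSF mean {r.mean:.3f}  std {r.std:.3f}  "
          f"nearest-centroid accuracy {exp[chan]['accuracy']:.2f}")
```

```
velocity  CSF mean 0.097  std 0.022  nearest-centroid accuracy 0.98
random    CSF mean 0.134  std 0.010  nearest-centroid accuracy 0.62
```

The velocity channel yields the lower CSF — its embedding represents the
three speed classes more meaningfully than the random channel's — and the
classes are separable by a nearest-centroid classifier in the 3-dimensional
embedding. Absolute CSF values depend on the compression backend; every
distance matrix records which backend produced it.

A `ssfembed` command-line tool exposes the stages (`phantom`, `ssf`, `ncd`,
`embed`, `csf`, `run`) for TIFF movies and CSV/JSON artifacts.

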