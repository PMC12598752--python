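# cofracnet

Protein interactome and protein-complex inference from co-fractionation
mass-spectrometry (CF-MS) elution profiles and protein sequences.

In a CF-MS experiment a cell lysate is separated into chromatographic
fractions and every fraction is quantified by mass spectrometry, giving each
protein an *elution profile* across fractions. Proteins bound in the same
complex co-elute, so their profiles correlate — but the signal is noisy,
resolution differs between experiments, and hand-crafted pair similarity
features discard information. `cofracnet` is for proteomics groups who want
to go from an elution matrix plus a FASTA file to a scored protein–protein
interaction (PPI) network and a set of predicted complexes, with evaluation
against a curated reference.

## The model

Each protein *i* gets one input row

```
x_i = [ e_i (200) | f_i + c_i (256) ]
```

where `e_i` is the sum-normalized elution profile zero-padded to 200
fractions, `f_i` is the flattened frequency-matrix chaos game representation
(FCGR) of its sequence (resolution 16 → 256 bins, contraction factor
0.863271, per-protein max-normalized), and `c_i` is a trainable protein
embedding updated by backpropagation, so complex-level label structure flows
into the representation during training.

A length-preserving 1-D convolution with *F* filters maps `x_i` to a feature
map `h_i ∈ R^{456×F}`, with the raw input re-added to every filter channel
(residual connection). A pair (i, j) is scored from `|h_i − h_j|`
concatenated with `|x_i − x_j|`, flattened and passed through three fully
connected layers into a logistic unit — so convolution cost scales with the
number of proteins *N*, not with the ~N²/2 pairs, and scores are symmetric
in pair order by construction.

Training pairs come from a reference complex catalog (complexes with ≥ 3
members): same-complex pairs are positive, pairs spanning distinct complexes
negative, and a nominal positive is relabeled negative when its profiles
never co-elute (per-fraction product never above 0.01). Negatives are
down-sampled 1:1 and evaluated by 5-fold cross-validation at a hard 0.5
threshold (sensitivity, specificity, MCC, ROC AUC).

Scored edges above 0.5 form a weighted graph that is smoothed two ways — a
Markov-cluster flow matrix (expansion 2, inflation 2, 3 iterations) and a
topological overlap matrix `w_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
on the elementwise 2.5th power of the adjacency. The two are blended
(0.3/0.7 and 0.1/0.9), clustered by Ward linkage on cosine row distances
with a dynamic tree cut (minimum cluster size 3), capped below 100 members,
and unioned; clusters with overlap score `|X∩Y|²/(|X||Y|)` above 0.25 are
merged. Predicted complexes are evaluated structurally (composite score =
overlap fraction + √(Sn·PPV) + maximum matching ratio), functionally
(edge-weighted GO semantic similarity with best-match averaging; c = 0.67,
d = 0.4 for is_a and 0.3 for part_of), and spatially (largest fraction of
members sharing a subcellular compartment), plus gradient saliency maps
attributing each prediction to the CF-MS or sequence input region.

## Worked example

The built-in generator plants complexes with shared elution apexes, shared
sequence motifs, one GO leaf term and one compartment per complex, so the
whole pipeline runs offline:

```python
from cofracnet.pipeline import run_synthetic_pipeline
from cofracnet.simulate import SimConfig

report = run_synthetic_pipeline(
    sim_cfg=SimConfig(noise_sd=0.0, missing_rate=0.0, seed=7),
    seed=7, n_random_clusterings=200, bootstrap_reps=5000, n_saliency_pairs=40,
)
cls, clu = report["classification"]["mean"], report["clustering"]
print(f"mean held-out accuracy : {cls['accuracy']:.3f}")
print(f"mean held-out AUC      : {cls['auc']:.3f}")
print(f"clusters found         : {clu['n_clusters']}")
print(f"composite score        : {clu['composite']:.3f} "
      f"(overlap {clu['overlap_frac']:.2f}, accuracy {clu['accuracy']:.3f}, "
      f"MMR {clu['mmr']:.3f})")
print(f"random-clustering p    : {clu['random_null']['empirical_p']:.4f}")
print(f"mean GOGO (BP)         : {report['gogo_bp_mean']:.3f}")
print(f"mean colocalization    : {report['colocalization_mean']:.3f}")
```

which prints:

```
mean held-out accuracy : 0.919
mean held-out AUC      : 0.971
clusters found         : 19
composite score        : 2.317 (overlap 0.84, accuracy 0.951, MMR 0.525)
random-clustering p    : 0.0050
mean GOGO (BP)         : 0.476
mean colocalization    : 0.630
```

Read: the 5-fold classifier separates planted from non-interacting pairs at
~92% held-out accuracy; the clustering stack recovers the 20 planted
complexes with a composite score of 2.32 out of 3, which none of 200
size-matched random clusterings approaches (empirical p = 0.005); and the
predicted clusters are functionally and spatially far more coherent than
chance (a random 4-member set scores ~0.35 on colocalization).

The same stages are exposed on the command line for file-based use
(`cofracnet simulate | preprocess | encode | label | train | predict |
cluster | evaluate | saliency | all`); every command takes an explicit
`--seed` and reruns reproduce outputs byte for byte.

## Layout

- `src/cofracnet/elution.py` — elution matrix I/O, normalization, padding
- `src/cofracnet/fcgr.py` — chaos-game sequence encoding
- `src/cofracnet/labels.py` — reference complexes, pair labels, CV folds
- `src/cofracnet/nn.py`, `classifier.py` — the pair-scoring network and
  sklearn-style estimator, cross-validation, co-training
- `src/cofracnet/clustering.py` — MCL, TOM, dynamic tree cut, merging
- `src/cofracnet/metrics.py` — classification, composite, GOGO,
  colocalization, bootstrap null
- `src/cofracnet/saliency.py` — gradient attribution
- `src/cofracnet/simulate.py` — seeded synthetic datasets
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
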