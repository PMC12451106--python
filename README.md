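# schsc — hard-sample-aware contrastive clustering for scRNA-seq

`schsc` clusters single-cell RNA-seq count matrices. It is aimed at the
standard cell-type-annotation setting: a sparse cells × genes matrix of
transcript counts, a known (or assumed) number of cell types K, and the need
for an unsupervised partition of the cells that respects both expression
profiles and the local neighborhood structure of the data.

Two properties of scRNA-seq data motivate the design. Dropout makes truly
similar cells look dissimilar (hard positives), and heterogeneous populations
can produce deceptively similar profiles across distinct types (hard
negatives). A contrastive learner that treats all pairs equally wastes most
of its gradient on pairs that are already easy; `schsc` instead reweights
pairs by how hard they are, using pseudo-labels as a surrogate supervisory
signal.

## Method

1. **Preprocessing** — filter genes/cells with fewer than `min_counts` total
   counts, scale each cell to the median library size, `log1p`, select the
   top *p* highly variable genes (binned normalized dispersion), and
   standardize each gene to zero mean and unit variance, giving
   X ∈ ℝ^{N×p}. Raw counts are retained for the reconstruction likelihood.
2. **Graph smoothing** — build a KNN cell graph A from X and apply the
   one-pass generalized Laplacian filter
   X_filtered = (I − L̃_sym) X = D̃^{−1/2} Ã D̃^{−1/2} X with Ã = I + A.
3. **Dual-view embeddings** — two independent attribute encoders map
   X_filtered to Z^{v1}, Z^{v2} ∈ ℝ^{m×d}; two structure encoders map the
   cells' adjacency rows to E^{v1}, E^{v2}. Rows are ℓ2-normalized, so the
   fused similarity
   S(i^{v_k}, j^{v_l}) = α·⟨Z_i^{v_k}, Z_j^{v_l}⟩ + (1−α)·⟨E_i^{v_k}, E_j^{v_l}⟩
   blends attribute and structure cosine similarities over the 2m stacked
   views.
4. **Hard-sample weighting** — Leiden (or Louvain) on the fused embedding
   Z = (Z^{v1}+Z^{v2})/2, with the resolution binary-searched to K, yields
   pseudo-labels P; the fraction τ of cells closest to their own pseudo-
   centroid forms the high-confidence set H. Within H×H each pair is
   weighted W = |Q_ij − Norm(S)|^β (Q_ij = 1 iff P_i = P_j, Norm = batch
   min–max), which up-weights hard positives/negatives and damps easy pairs;
   pairs outside H×H keep weight 1.
5. **Loss** — an InfoNCE over the weighted logits S·W (positive = the same
   cell's other view, negatives = all other cells in both views), averaged
   over the 2m anchors (L_Hs), plus a zero-inflated negative binomial
   reconstruction term: three decoder heads on Z produce
   Π = sigmoid(ZW_π), M = exp(ZW_μ) scaled by per-cell size factors,
   Θ = exp(ZW_θ), and L_ZINB = −Σ_ij log ZINB(x_ij^raw; π_ij, μ_ij, θ_ij).
   The total is L = L_Hs + ω·L_ZINB with ω dynamically matched to the loss
   scales (or fixed by the user).
6. **Assignment** — all cells are embedded, and Louvain on a KNN graph of
   the embeddings (resolution again binary-searched to K) gives the final
   clusters, scored by ACC / NMI / ARI against labels when available, or by
   compactness and separation without them.

The networks are trained with a small built-in reverse-mode autodiff engine
on numpy (float64, single-threaded, bitwise reproducible under a seed); no
deep-learning framework is required.

## Worked example

```python
import schsc
from schsc.training import TrainConfig, train
from schsc.inference_metrics import (embed_all, final_clustering, nmi_ari,
                                     clustering_accuracy, compactness_separation)

spec, counts, labels, _ = schsc.fixture_small()          # 500 cells, 5 clusters
data = schsc.preprocess(counts, p=2000)                  # keeps all 300 genes
model, history, graph, X_filtered = train(data, TrainConfig(K_target=5))
emb = embed_all(X_filtered, graph.adjacency_sym, model)
result = final_clustering(emb, k=15, K_target=5)

nmi, ari = nmi_ari(result.labels, labels)
comp, sep = compactness_separation(emb, result.labels)
print(f"epochs trained : {history.n_epochs}")
print(f"final loss     : {history.total[-1]:.3f} ...")
print(f"NMI={nmi:.3f}  ARI={ari:.3f}")
```

Output (about a minute on one CPU):

```
epochs trained : 121
final loss     : 13.534 (L_hs=6.781, L_zinb=151505.3, omega=4.46e-05)
clusters found : 5 at resolution 1.250
NMI=1.000  ARI=1.000  ACC=1.000
compactness=0.417  separation=1.246
```

The planted 5-cluster structure is recovered perfectly (ARI/NMI/ACC = 1):
the early stop fires after 121 epochs once the total loss plateaus, the
dynamic ω (~4.5e−5) balances the summed ZINB likelihood (~1.5e5) against the
contrastive term (~6.8), and the resolution search lands Louvain exactly on
5 communities.

The same pipeline is available from a shell:

```bash
schsc simulate --preset small --out data/
schsc train --input data/ --format mtx --n-clusters 5 --out run/
schsc cluster --embeddings run/embeddings.csv --n-clusters 5 \
      --labels data/labels.tsv --out clustered/
```

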