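# rbfgcn

Staging Alzheimer's disease from attributed structural brain networks with a
regional brain fusion graph convolutional network (RBF-GCN).

## The problem

Each subject is represented by an undirected weighted graph over the 148
cortical regions of the Destrieux atlas (74 per hemisphere): edge weights
are white-matter fiber counts from diffusion tractography, and each region
carries its amyloid SUVR (PET tracer uptake relative to cerebellum, a proxy
for amyloid-β burden). The task is to predict the subject's clinical stage —
normal control (NC), mild cognitive impairment (MCI), or Alzheimer's disease
(AD) — as a graph-level classification, and to quantify two properties of
the disease that motivate the architecture: region-specific amyloid
affinity, and left/right hemispheric asymmetry of both amyloid and network
topology.

The package is aimed at network-neuroscience and machine-learning
researchers who want a self-contained, CPU-only reference implementation:
it ships a synthetic cohort generator that emulates the relevant population
structure, so every analysis runs end-to-end with no access to restricted
neuroimaging data.

## The model

A graph-convolution layer propagates node features with the
symmetric-normalized adjacency with self-loops:

    H⁽ᵏ⁺¹⁾ = σ(D̃^{-1/2} (A + I) D̃^{-1/2} H⁽ᵏ⁾ W⁽ᵏ⁾),   H⁽⁰⁾ = F.

Two ideas extend this baseline:

* **ANNA unit** (adaptive native node attribute): a learnable scalar α per
  layer re-injects each node's own attributes next to the neighborhood
  aggregate, `H⁽ᵏ⁺¹⁾ = σ((S H⁽ᵏ⁾ + α⁽ᵏ⁾ H⁽ᵏ⁾) W⁽ᵏ⁾)` — preserving the
  region-specific attribute contrast that smoothing destroys. At α = 0 it
  is exactly the plain layer.
* **RBF framework** (regional brain fusion): three independent channels
  process the full brain and the left/right hemispheric subnetworks
  `A_l = Λ_l A Λ_lᵀ`, `A_r = Λ_r A Λ_rᵀ` (Λ are binary half-selectors);
  each channel's node map is mean-pooled to a 32-vector and the three are
  fused by concatenation `[h_f, h_l, h_r]` or element-wise addition before
  a 2-layer MLP with softmax.

Training: NLL loss, Adam (lr 1e-3), batch 20, Xavier-normal init,
stratified 10-fold cross-validation; binary tasks report ACC/SEN/SPE with
the more severe diagnosis as the patient class, the three-way task reports
accuracy. The neural stack is pure numpy with hand-written backprop,
verified against finite differences to ~1e-10.

The package also reproduces the supporting statistics: per-region
amyloid differences between diagnostic cohorts, six weighted graph measures
(strength, betweenness, Onnela clustering, PageRank, participation
coefficient, within-module degree z-score), and paired Wilcoxon signed-rank
tests between homologous left/right regions. See `docs/methods.md` for
definitions, conventions and caveats.

## Worked example

`examples/03_train_and_cross_validate.py` generates a desk-scale cohort
(20 regions, 150 subjects), then cross-validates the baseline GCN and the
full RBF-GCN on the three-way task:

```
baseline   multiclass ACC = 60.67 ± 10.11
rbf_gcn_c  multiclass ACC = 66.67 ± 6.67
```

The numbers are mean ± sd of accuracy (%) across 5 folds: the fused
three-channel model with ANNA beats the single-channel baseline by several
points on the same data. `examples/04_lateralization_analysis.py` prints
the paired left/right tests on a cohort with hub-concentrated asymmetry:

```
amyloid left-right asymmetry: p = 7.89e-14
  within_module_z    W=    889.0  p=7.30e-03 *
  strength           W=      0.0  p=7.89e-14 *
  betweenness        W=    255.0  p=4.65e-05 *
  participation      W=      0.0  p=7.89e-14 *
  clustering         W=      0.0  p=7.89e-14 *
  pagerank           W=    499.0  p=1.72e-06 *
```

Every measure is significantly lateralized (p < 0.05), matching the
asymmetry planted by the generator. The other examples cover cohort
simulation/IO (`01`) and hemispheric extraction plus a single forward pass
(`02`).

A thin CLI wraps the same library:

```bash
rbfgcn simulate --scaled --seed 1 --out-dir data/
rbfgcn evaluate --manifest data/manifest.yaml --task NC_vs_AD \
       --arm rbf_gcn_c --epochs 100 --folds 5 --hidden 16 --out-dir results/
rbfgcn analyze --manifest data/manifest.yaml --out-dir results/
rbfgcn reproduce-ablation --seed 1 --out-dir results/   # all six arms
```

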