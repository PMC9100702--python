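# Methods

## Problem and data model

The package classifies the clinical stage of Alzheimer's disease — normal
control (NC), mild cognitive impairment (MCI), or AD — from one attributed
structural brain network per subject. A network has `m = 148` nodes, the
cortical regions of the Destrieux parcellation (74 per hemisphere; nodes
1–74 are left-hemisphere by convention, 75–148 right, homologous regions at
offset 74). Edge weights are streamline (fiber) counts from diffusion
tractography: the adjacency `A` is symmetric, nonnegative, with zero
diagonal. Node attributes `F` (an `m × d` matrix) carry the regional amyloid
SUVR in the first column — PET tracer uptake relative to cerebellum, a
proxy for amyloid-β burden. Raw fiber counts are used without thresholding
or normalization beyond the graph-convolution normalization described below.

## Model

### Graph convolution and the ANNA unit

Each layer propagates node features with the symmetric-normalized adjacency
with self-loops,

    S = D̃^{-1/2} (A + I) D̃^{-1/2},     D̃_ii = Σ_j (A + I)_ij,
    H^(k+1) = σ(S H^(k) W^(k)),          H^(0) = F.

The adaptive native node attribute (ANNA) unit re-injects each node's own
features next to the neighborhood aggregate through one learnable scalar
per layer:

    H^(k+1) = σ((S H^(k) + α^(k) H^(k)) W^(k)).

At `α = 0` the ANNA layer is exactly the plain layer. The gain is
unconstrained and initialized at 0, so training starts from the plain-GCN
point and learns the native-attribute contribution from data. Amyloid
burden attacks specific regions; aggregation smooths exactly the per-region
contrast that carries that signal, which is what the native path preserves.

### Regional brain fusion (RBF)

Three parameter-independent channels process the full brain and the two
hemispheric subnetworks `A_l = Λ_l A Λ_lᵀ`, `A_r = Λ_r A Λ_rᵀ`,
`F_l = Λ_l F`, `F_r = Λ_r F` (binary selectors pick the first and second
halves of the node order; inter-hemispheric edges survive only in the
full-brain channel). Each channel runs 3 graph-convolution layers of 32
hidden units, then global mean pooling over nodes yields one 32-vector per
graph. Mean pooling is chosen because it makes the 148-node and 74-node
channels commensurate, which the addition fusion requires; sum and max
pooling are available as options. The three vectors are fused by
concatenation (`[h_f, h_l, h_r]`, width 96) or element-wise addition
(width 32), then a 2-layer MLP with 32 hidden units and log-softmax
predicts the stage.

Six ablation arms are expressible from the configuration: `baseline`
(full-brain channel only, plain GCN), `anna` (full-brain + ANNA), `rbf_c` /
`rbf_a` (three plain channels, concat/add fusion), and `rbf_gcn_c` /
`rbf_gcn_a` (three ANNA channels). The baseline arm shares readout and MLP
with every other arm so comparisons isolate the component under test.

### Architectural choices left open by the design

The nonlinearity σ is ReLU in every graph-convolution layer (including the
last, before pooling) and in the MLP hidden layer; configurable.
Graph-convolution layers carry no bias; the MLP does. No dropout or weight
decay by default. When `add_node_identity` is on (the default), a one-hot
node-identity block is appended to the attributes of each channel's input;
without some form of positional information a weight matrix shared across
nodes cannot express region-specific attribute effects, which is the
mechanism the ANNA unit is designed to exploit.

## Training and evaluation

Negative log-likelihood loss, Adam (lr 1e-3), minibatches of 20 subjects,
Xavier-normal initialization, 500 epochs at full scale; final-epoch
parameters are evaluated (no validation split or early stopping is used).
The neural stack is implemented directly over numpy with hand-written
backpropagation; gradients are verified against central finite differences
to better than 1e-5 (observed ~1e-10) for every weight matrix, every ANNA
gain and the MLP parameters.

Evaluation uses stratified k-fold cross-validation (k = 10 at reference
scale). Stratification is used so that small cohorts keep all classes in
every test fold. Binary tasks take the more severe diagnosis as the
"patient"/positive class and report

    ACC = (TP+TN)/(TP+FN+TN+FP),  SEN = TP/(TP+FN),  SPE = TN/(TN+FP);

a zero denominator yields an undefined-metric marker (`None`), not an
exception. The three-way task reports accuracy only. Fold summaries are
mean ± sample (n−1) standard deviation. Predictions are the argmax of the
class log-probabilities with ties broken toward the lower class index.

## Lateralization statistics

Three analyses connect the architecture to the data:

1. **Regional amyloid differences**: per-region difference of cohort-mean
   SUVR between diagnostic groups (NC vs AD, MCI vs AD, NC vs MCI).
2. **Six weighted graph measures** per node: strength (weighted degree,
   row sum), betweenness on edge lengths `1/w` (unnormalized), Onnela
   weighted clustering, PageRank (damping 0.85), participation coefficient
   `P_i = 1 − Σ_s (κ_is/k_i)²`, and the within-module degree z-score of
   intra-module strength (population-sd standardization per module).
   Modules come from Louvain modularity maximization with a fixed seed,
   detected on the homologous-average hemispheric topology so module labels
   are shared between sides. These are the most widely used weighted forms;
   each is a deliberate choice where several variants exist.
3. **Paired Wilcoxon signed-rank tests** between homologous left/right
   regions, two-sided, for mean SUVR and each measure. Zero differences are
   dropped, ties get mid-ranks; the exact null distribution is used up to
   25 nonzero pairs and the normal approximation with continuity correction
   beyond. An all-zero difference vector returns a degenerate result with
   p = 1.

By default the topological comparison is computed on the population-mean
adjacency ("population" mode); "subject" mode computes per-subject measures
and averages them per region before pairing.

**Caveat on cohort-level null calibration.** The 74 paired measure values
derive from a single pair of hemisphere graphs and are therefore mutually
correlated (e.g., a chance excess of total right-hemisphere weight shifts
every strength pair together). The signed-rank test assumes independent
pairs, so its cohort-level type-I rate for topological measures exceeds the
nominal level even under a symmetric generator (~15% pooled in our checks).
This is an inherent property of this style of analysis, not of the
implementation; the amyloid test, whose node noise is independent, is
calibrated at the nominal rate, and the test itself is exactly calibrated
for independent pairs (verified against enumeration of all sign patterns).

## Synthetic cohort generator

No public accession exists for the study data, so the generator emulates
its documented statistical structure. Defaults produce 502 subjects
(168 NC / 165 MCI / 169 AD) with 148 regions.

*Topology.* Fiber counts are negative-binomial (dispersion r = 2, variance
μ + μ²/r — over-dispersed, integer, nonnegative) with expected weight
decaying with inter-regional index distance, `μ(i,j) = 30·exp(−|i−j|/ℓ)`
within hemispheres (ℓ = 0.15·74) and `3·exp(−|i−j|/ℓ)` between homologous
cross-hemisphere indices, so intra-hemispheric blocks are denser than the
callosal block. The right hemisphere's decay length is scaled by
`lateralization_effect = 1.3` (systematically longer-range connectivity).
Optionally (`lateralization_hubs > 0`) a few evenly spread right-hemisphere
regions get their connectivity multiplied by the same factor; this
hub-concentrated asymmetry also moves scale-invariant measures (PageRank,
within-module z-score) that a block-wide rescaling leaves nearly unchanged,
and is what the "all six measures lateralized" power check exercises. With
`lateralization_effect = 1` the hemispheric blocks are exchangeable.

*Amyloid.* Each subject draws a continuous severity `s ~ N(stage, 0.6)`
around its discrete stage (0/1/2). SUVR per region is

    base 1.2 + clip(s,0,1)·early_j + clip(s−1,0,1)·late_j
    ± (0.04 + 0.05·stage)  [+ left, − right]
    + subject offset N(0, 0.08) + node noise N(0, 0.20),  clipped ≥ 0.05.

The early profile (burden added NC→MCI) and late profile (added MCI→AD)
place 0.5- and 0.36-high affinities on interleaved region sets (every 5th
region, mirrored across hemispheres) over a 0.05 floor — the disease
attacks regions in a sequence, and affinity is rough with respect to the
distance-banded connectivity. The hemispheric amyloid offset grows with
stage, reflecting disease-dependent left/right asymmetry of amyloid
accumulation. Passing an explicit `affinity_profile` splits it evenly
between the two steps.

*Calibration.* The severity jitter and subject offset keep adjacent stages
overlapping: the single-channel baseline reaches roughly 84–86% NC-vs-AD
accuracy and 55–62% three-way accuracy at desk scale — learnable but far
from separable — leaving measurable headroom for the ANNA unit and the RBF
framework. What the generator does **not** model: real tractography error
structure, spatial (geometric) embedding of regions, atrophy, demographic
covariates, or any coupling between a subject's topology and its amyloid
levels. Passing checks on this cohort therefore demonstrate correctness and
qualitative behavior of the method, not clinical performance.

## Desk-scale experimental protocol

The reference protocol (148 regions, 502 subjects, 500 epochs, 10-fold CV)
is supported but slow on one CPU; for the package's own regression checks a
fixed scaled protocol is used: 20 regions, 50 subjects per stage (n = 150),
100 epochs, 5-fold stratified CV, 16 hidden units, multiclass task, five
seed replicates (each replicate regenerates the cohort and reseeds
training). Under this protocol the mean CV accuracy ordering
RBF-GCN(C/A) ≥ ANNA ≥ baseline is required to hold in at least 4 of 5
replicates; arm differences of a few points ride on fold-level noise of
similar size, which is why the criterion is an ordering over replicates
rather than a fixed margin.

## Numerical conventions

* Adjacency read repair: asymmetry up to 1e-6 is averaged away
  (`(A+Aᵀ)/2`), larger asymmetry is an error; nonzero diagonals are zeroed
  with a warning. Self-loops exist only inside the GCN normalization.
* Round-trips through CSV and GraphML preserve matrices to 1e-12 (17
  significant digits on disk).
* PageRank power iteration runs to tolerance 1e-12 (up to 5000 iterations).
* Isolated nodes: strength 0, clustering 0, participation 0; a module with
  zero strength variance gives z = 0 to its members.
* Degenerate confusion denominators yield `None` metrics, excluded from
  fold averages.
* All randomness flows from explicit integer seeds (numpy `default_rng`);
  same seed ⇒ byte-identical cohorts on disk and identical training traces.

## Known limitations

* Full-scale training (500 epochs × 10 folds × 502 subjects at m = 148) is
  expensive on one CPU; the scaled protocol is the practical default.
* The multiclass problem at desk scale sits in a regime where arm
  differences are small relative to fold noise; single-replicate
  comparisons are not meaningful.
* The Wilcoxon caveat above applies to any reading of the cohort-level
  topological lateralization p-values.
* The generator's hemispheric convention ties homologous regions to equal
  indices; data in other orderings must supply a manifest permutation.
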