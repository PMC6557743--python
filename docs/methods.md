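# Methods

## Problem setting

The package predicts drug–target interactions from three inputs: a binary
adjacency matrix **Y** ∈ {0,1}ⁿˣᵐ over n drugs and m targets, a drug–drug
chemical similarity matrix **S**ᵈ ∈ [0,1]ⁿˣⁿ, and a target–target sequence
similarity matrix **S**ᵗ ∈ [0,1]ᵐˣᵐ. A 0 in **Y** is ambiguous — it may be a
tested non-interaction or an untested pair — which motivates both the WKNKN
imputation and the weighted (W-masked) engines. The core modelling assumption
is the manifold/guilt-by-association hypothesis: drugs with similar chemical
structure tend to share targets, and targets with similar sequence tend to
share drugs, so the latent rows of similar entities should be close.

## Factorization engines

Every engine seeks **A** ∈ ℝⁿˣᵏ, **B** ∈ ℝᵐˣᵏ with **Y ≈ ABᵀ** and scores
pair (i, j) by aᵢ·bⱼ. The objectives are stated in the README; what matters
numerically:

* **Initialization.** Truncated SVD of Y: A = U S_k^{1/2}, B = V S_k^{1/2},
  singular values descending. Signs are fixed by making the largest-magnitude
  entry of each left singular vector positive, so runs are bit-reproducible.
  k may not exceed min(n, m).
* **Updates.** Alternating closed-form least squares. The unweighted engines
  use matrix updates, e.g. for the graph family
  A ← (YB − λ_d L̃ᵈ A)(BᵀB + λ_l I_k)⁻¹,
  where the Laplacian term uses the previous-iterate A (a lagged fixed-point
  scheme — the printed closed forms are only consistent that way). The
  weighted engines solve one k×k system per row:
  aᵢ ← (Σⱼ W_ij Y_ij bⱼ − λ_d (L̃ᵈ)ᵢ· A)(Σⱼ W_ij bⱼᵀbⱼ + λ_l I_k)⁻¹,
  batched over rows. In CMF, the similarity-fitting Gram terms (λ_d AᵀA,
  λ_t BᵀB inside the inverses) are likewise lagged.
* **L2,1 term.** ‖B‖₂,₁ is handled by IRLS: per-row weights
  d_jj = 1/(2·max(‖bⱼ‖₂, ε)) computed from the current B enter the row-j
  update as an extra ridge λ_s d_jj I_k. The shared Gram matrix AᵀA is
  eigendecomposed once per sweep so all m row systems are solved in one
  vectorized pass. The zero-row guard ε = 1e-8 keeps d_jj finite; with
  λ_s = 0 the same code path reduces exactly to GRMF.
* **Stopping.** Relative objective change < `tol` (default 1e-4) or
  `max_iter` (default 200). Because the Laplacian/IRLS terms are lagged,
  monotone descent is not guaranteed in theory; every engine aborts loudly if
  the objective goes non-finite, and descent is asserted empirically on the
  planted benchmark. Iterating with a much tighter tolerance (1e-14) drives
  the frozen-coefficient normal-equation residuals to ~1e-6·‖Y‖_F, i.e. the
  iteration does converge to a fixed point of its own update maps.
* **Degenerate systems.** A singular k×k system falls back to least squares
  with a warning. Isolated graph nodes (zero degree after sparsification) get
  zero rows in the normalized Laplacian, so their updates reduce to ridge
  regression.

Default hyperparameters: k = 50 (clipped to min(n, m) by the CV driver and
CLI), λ_l = 0.5, λ_d = λ_t = 0.1, λ_s = λ_l (coupled unless set), p = 5.
λ_l's grid {2⁻², 2⁻¹, 2⁰, 2¹} is what the CV grid search sweeps by default;
λ_d, λ_t, λ_s and k can be added to the grid through `CVConfig.grid`.

## Graph construction

Similarities are sparsified before regularization: N_p(i) is the set of the p
indices j ≠ i with largest S_ij (ties toward the smaller index, for
determinism); N_ij is 1 for mutual neighbors, 0.5 one-sided, 0 otherwise,
with N_ii = 0 — with unit diagonals every node would otherwise be its own
nearest neighbor and the graph would carry self-loops only. Ŝ = N ⊙ S, then
D_ii = Σⱼ Ŝ_ij, L = D − Ŝ, L̃ = D^{-1/2} L D^{-1/2} (rows of isolated nodes
zeroed). Neighbors are selected by largest similarity, not smallest Euclidean
distance: the inputs are similarity matrices, and the neighbor-set definition
is written over S itself.

## WKNKN imputation

A drug (target) is *known* if it has ≥ 1 recorded interaction in the current
— possibly masked — training matrix; the known set is recomputed inside every
CV fold so no test information leaks in. For drug d with the K most similar
known drugs d₍₁..K₎ (self excluded, ties by index):

    Yd(d,:) = (1/Z_d) Σ_l η^{l−1} Sᵈ(d, d₍l₎) Y(d₍l₎,:),   Z_d = Σ_l Sᵈ(d, d₍l₎)

Yt analogous on columns; output = max(Y, (Yd + Yt)/2), elementwise. Known 1s
are preserved and the output dominates the input. Defaults K = 5, η = 0.7.
Note the normalizer sums raw similarities (not η-decayed ones), so the K = 2,
η → 0 estimate approaches S₁Y₁/(S₁+S₂), a *shrunk* single-neighbor rule
rather than the K = 1 value exactly; the tests assert the corresponding
one-sided bound.

## Evaluation protocol

CVd partitions drug rows, CVt target columns, into ten seeded near-equal
folds; masking zeroes whole rows/columns and every cell of the masked block
is a test entry. Per fold: mask → optional WKNKN on the training matrix →
inner 3-fold CV on the training block only (test entities removed entirely)
choosing the grid combination with the best mean inner AUPR → fit on the full
masked matrix → score test cells with ABᵀ. For the weighted engines, W is 1
except on the masked block. Fold AUPRs are averaged per repeat; the protocol
repeats five times with fresh partitions (per-repeat seeds spawned from the
master seed) and reports mean ± sd over the five repeat means. Folds whose
test block has no positive are skipped with a warning — AUPR is undefined
there — rather than scored zero.

AUPR is the step-wise, non-interpolated area Σᵢ (Rᵢ − Rᵢ₋₁)·Pᵢ over distinct
score thresholds with ties grouped — the dominant convention in this
literature, and the one pinned by the exhaustive-threshold oracle tests. AUC
is the Mann–Whitney statistic with ties counted 0.5. AUPR is primary because
interactions are rare (~1–10% prevalence): a random ranking scores ≈
prevalence on AUPR but 0.5 on AUC.

## Synthetic benchmark

The generator plants the exact structure the models assume: latent factors
A\* ∈ ℝⁿˣᵏ, B\* ∈ ℝᵐˣᵏ drawn i.i.d. standard normal; Y gets 1s at the
⌈density·n·m⌉ largest entries of A\*B\*ᵀ (so with zero noise every
interacting pair out-scores every non-interacting one); similarities are RBF
kernels on the latent rows with bandwidth = median pairwise distance
(scale-free), min–max rescaled to [0,1], plus truncated symmetric Gaussian
noise, unit diagonal. Defaults n = 60, m = 40, k_true = 4, density = 0.1,
noise sd = 0.1 — prevalence in the range of the denser public benchmarks and
enough entities for ten-fold splits on both axes, while a full five-repeat CV
with grid search runs in seconds. Entities that end up with no interactions
are kept: they model never-tested drugs/targets, exactly what CVd/CVt
simulates; only a completely empty Y is redrawn.

What the generator does *not* emulate: block/community structure of real
target families, hub drugs with extreme degree, similarity matrices computed
from actual fingerprints or alignments (with their heavy-tailed, sometimes
barely-informative distributions), and batch correlation between the two
similarity spaces. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted manifold-consistent structure — not
expected performance on any particular real dataset.

## Design choices made where the design was open

* The printed B-update of the L2,1 model couples a diagonal m×m matrix with a
  k×k inverse; the only dimensionally consistent reading is the standard
  per-row IRLS form, which also matches the weighted variant's explicitly
  row-wise update. Implemented that way.
* The printed CMF A-update places AAᵀ (n×n) inside a k×k inverse; read as
  AᵀA, the Gram matrix the derivation produces.
* The L2,1 coefficient is exposed as λ_s defaulting to λ_l: the printed
  objectives reuse λ_l for both the Tikhonov and the sparsity term, and the
  default preserves that coupling while letting the sparsity pressure be
  tested independently.
* Normalized Laplacians are used in all graph engines' objectives and
  updates, including the weighted ones.
* CMF runs unweighted by default; the weighted data term is available by
  passing W.
* Ranking ties (equal scores) break toward the smaller index everywhere, for
  reproducibility.

## Known limitations

* The lagged alternating scheme has no descent guarantee; pathological
  hyperparameters (very large λ_d with a hostile graph) could oscillate. The
  non-finite-objective abort is the safety net.
* Entities with neither interactions nor informative similarities are
  unpredictable in principle; the models fall back to ridge shrinkage toward
  zero for them.
* The weighted engines solve n + m k×k systems per sweep and are roughly an
  order of magnitude slower than the matrix-update engines at these sizes.
* WKNKN can inject misleading values when the similarity space is
  uninformative for a given entity; it is deliberately optional and refit
  per fold.
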