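# Methods

## Model

Spot-level spatial transcriptomics data are arranged as a nonnegative
third-order tensor `T ∈ R+^(ny×nx×ng)`: two axes index the spot grid
(y-row, x-column) and the third indexes genes.  The package fits the
masked, graph-regularized nonnegative Tucker decomposition

    min_{G, Ay, Ax, Ag ≥ 0}  ½‖M ⊙ (T − T̂)‖²_F + (λ/2)·vec(T̂)ᵀ L_c vec(T̂),
    T̂ = ⟦G; Ay, Ax, Ag⟧ = G ×1 Ay ×2 Ax ×3 Ag,

where `M` is a binary mask selecting observed entries, `G` is the
`(ry×rx×rg)` core holding the weight of every multiway interaction among
spatial and gene components, and `L_c = Lg ⊕ Ly ⊕ Lx` is the Kronecker-sum
Laplacian of the Cartesian product of three graphs: unweighted chain graphs
along y and x (adjacent spots) and a gene interaction network (e.g. a
protein–protein interaction network).  The penalty encodes the two priors
the data layout suggests: expression varies smoothly between adjacent
spots, and interacting genes share similar spatial expression.

### Optimization

Each block (Ay, Ax, Ag, then G, in that order) is updated in turn by a
multiplicative rule: every entry is multiplied by the ratio of the negative
to the positive part of that block's gradient,

    A ← A ⊙ (∂F₁⁻ + λ∂F₂⁻) / (∂F₁⁺ + λ∂F₂⁺ + ε).

The split takes the `M⊙T̂` term of the data residual as the positive part
and the `M⊙T` term as the negative part; the regularizer splits along
`L = D − W` into degree (positive) and adjacency (negative) parts.  All
four parts are elementwise nonnegative, so nonnegativity is preserved, and
each block update does not increase the objective (the usual majorization
argument for quadratic objectives with nonnegative structure; the test
suite checks monotonicity empirically over hundreds of sweeps).
Correctness of the gradient algebra is anchored to a central
finite-difference oracle rather than to a particular layout.

Gradients are evaluated through the Tucker structure.  The data term uses
contractions of `M⊙T̂` and `M⊙T` with the two fixed factors; the
regularizer touches one factor through its mode's Laplacian while the
other modes enter only through `r×r` Gram matrices.  The product Laplacian
(order `ny·nx·ng`) is never materialized; its quadratic form is evaluated
as the sum over modes of `⟨T̂, T̂ ×m L_m⟩`, and the tiny-instance tests
verify that this equals the explicit Kronecker-sum form.

After every sweep each factor column is rescaled to sum to one and the
scales are absorbed into the core (`G ← G ×1 U ×2 V ×3 W` with diagonal
column-sum matrices), leaving `T̂` unchanged while making core magnitudes
comparable across interactions.  Columns that collapse to zero are left
as zeros with unit scale — a dead component is a legitimate outcome, and
a warning is logged.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `rank` | (50, 50, 50) | components per mode; component analysis typically uses spatial ranks well above the number of tissue domains and gene rank equal to it |
| `lambda_` | 0.1 | regularization strength; 0.1 is a stable choice for imputation, 1.0 emphasizes smooth, domain-aligned components |
| `max_iter` | 5000 | sweep budget; component structure typically stabilizes by a few thousand sweeps |
| `tol` | 1e-4 | stop when the relative objective change `abs(f_k − f_{k−1})/max(f_{k−1}, 1)` falls below this |
| `seed` | 0 | i.i.d. uniform(0,1) initialization of all blocks |
| `eps` | 1e-12 | additive guard in multiplicative denominators against 0/0; entries at exactly zero stay zero by the multiplicative form |

The residual is defined on the relative objective change because it is
scale-free; an absolute criterion would be meaningless across tensors of
different size and depth.

### Spatial components

Contracting the core with the spatial factors, `Gxy = G ×1 Ay ×2 Ax`,
leaves one `(ny×nx)` activity map per gene component; applying the gene
factor along the component axis recovers `T̂` exactly, which is the
identity the implementation is tested against.  A sparse core (largest
n% of entries by value, `k = ceil(n/100 · #entries)`, ties broken by flat
index) isolates the dominant multiway interactions before the maps are
built; components should be built from the normalized model so core
magnitudes are comparable.  Regions are matched to components by minimal
Euclidean distance after normalizing both maps to unit length; AUC of the
component values against the binarized region is reported alongside.
Several regions may match the same component.

## Preprocessing

Visium arrays are hexagonally packed with matching row/column parity.
`y = array_row`, `x = (array_col − array_row mod 2)/2` places spots on a
square grid; the mapping is asserted injective on every input.  Cleaning
follows the standard order: entries below 3 UMI are zeroed, genes with
total UMI below 4 (after zeroing) are dropped, grid rows/columns with no
spots are cropped, and entries are transformed by natural `log(1+x)`.
The natural logarithm is used; the base only rescales the tensor.
The default mask marks nonzero entries of the final tensor as observed —
dropout zeros count as missing, which is what makes imputing complete
expression meaningful — with an `in-tissue` alternative that treats every
gene at every occupied spot as observed.

## Evaluation protocol

Cross-validation is spotwise: eligible spots (in-tissue, nonzero total
expression) are partitioned into five folds; each fold's spots have all
gene entries removed from the training mask.  Held-out entries that were
observed in the truth are scored with MAE, MAPE (restricted to positive
truth, otherwise undefined on sparse data), and R² computed within spots:
residuals and totals are centered per spot across its scored genes and
pooled over spots, R² = 1 − Σ_s SSres_s / Σ_s SStot_s — the per-spot
centering measures how well a spot's imputed expression profile matches
its original one, and pooling weights each spot by its truth variance.
An unweighted mean of per-spot R² values was rejected: with ~12%
density a held-out spot contributes only a handful of scored genes, and
spots whose few truth values are nearly equal by chance produce
arbitrarily negative ratios that dominate the mean.  Segmentation uses k-means (10
restarts, seeded) on each spot's component-coefficient vector, scored by
ARI against reference labels.

## Synthetic data

The generator plants exactly the structure the model assumes, with known
ground truth:

- **Spatial factors** come in two profiles.  The default `plateau`
  profile uses soft-edged plateau bumps: the chain splits into contiguous
  bands with jittered boundaries and logistic edges of ~1.5 spots.  Real
  annotated domains (cortical layers, tumor regions) are blocky plateaus
  that tile the tissue, and tiling makes the planted domain label of
  every spot well-defined; isolated blobs would leave most of the slide
  ambiguously labeled.  The `bump` profile uses overlapping discretized
  Gaussians at stratified random centers — the generic smooth low-rank
  regime, appropriate for optimization-behavior studies such as
  exact-rank recovery, where the near-disjoint column supports of the
  plateau profile create long multiplicative-update saddles (mass cannot
  flow across near-zero factor entries, so a mis-assigned band takes
  thousands of sweeps to swap).
- **Core**: each gene component rides one (y-band, x-band) tile, assigned
  by a diagonal-shifted enumeration so no two components share a spatial
  position (near-collinear components make the instance degenerate) while
  every band of both axes is touched — the tensor has full multilinear
  rank.  The plateau profile adds small random off-tile mass so the core
  is not trivially CP; the bump profile adds a dense low-level background
  populating every multiway interaction.
- **Gene factor**: each gene loads ~uniform(0.5, 1) on one dominant
  component plus a small background loading on one other.
- **Noise**: multiplicative Gaussian with CV 0.5 by default — the Poisson
  coefficient of variation of UMI counts in the 3–10 range that dominates
  observed Visium entries.  Near-noiseless settings are a degenerate
  regime for imputation experiments: an exact-low-rank tensor is then
  interpolated perfectly without regularization, so the λ-benefit the
  method exists for has nothing to act on.
- **Dropout**: entries below an expression floor (0.1, the analogue of
  the sub-3-UMI zeroing real pipelines apply) are never observed — a real
  experiment cannot report a fraction of a count, and treating logistic
  tail values of ~1e-10 as observations would make percent-error metrics
  meaningless.  The remaining entries are kept i.i.d. with the
  probability that hits the density target, 0.12 by default — the top of
  the range seen on real Visium sections, appropriate at this scale
  because the shrunken gene axis (60 genes vs ~11k) leaves far fewer
  observations per component.  `density=1` requests the fully observed
  ideal tensor and disables the capture model entirely.
- **Network**: genes sharing a dominant component are connected by a
  sparse within-module pattern (~2 edges/gene) plus 20% random distractor
  edges.  Dense module cliques were deliberately avoided: the Laplacian
  penalizes magnitude differences between connected genes, and a clique
  flattens the loading variation within a module.
- **Regions** are level sets (>50% of max) of single true spatial
  components; planted labels are the per-spot argmax over true
  components.

What passing tests on these fixtures do *not* show: robustness to
count-model misspecification (no Poisson/NB sampling), platform artifacts,
within-domain expression gradients, or networks whose modules do not align
with expression components.  Default study sizes — 40×40×60 slide for the
CV and component experiments, 30×30×100 for exact-rank recovery — were
chosen as the smallest slides that keep ≥100 spots per planted domain and
a spot:gene ratio above 25, so that the spotwise protocol and the
domain-level metrics remain meaningful.

## Numerical choices and limitations

- Unfolding uses C-order with remaining modes cycling in increasing order;
  any convention works as long as fold/unfold and the update algebra share
  it, which the roundtrip tests pin down.
- The multiplicative ε only guards 0/0; it does not move entries off zero.
- Multiplicative updates converge linearly and can crawl near
  ill-conditioned optima; component analyses should run a few thousand
  sweeps (under-converged fits tend to merge adjacent domains).
- Rank selection is manual; dead components (zero columns) are reported,
  not pruned.
- The λ=0 path is exactly unregularized nonnegative Tucker decomposition:
  the graph terms never enter the updates, which the suite checks by
  bit-comparing fits with and without a network.
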