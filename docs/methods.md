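# Methods

## Model

A grid cell is idealised as a superposition of three plane waves whose unit
wave vectors `k_1 = (1, 0)`, `k_2 = R₆₀k_1`, `k_3 = R₆₀k_2` are separated by
60°:

    g_i(r) = 1/3 + (2/9) Σ_{j=1..3} cos(2πf R_init k_j · (r − φ_i)),

with spatial frequency `f` (default 1 cycle per unit length), a rigid
orientation offset `R_init`, and per-cell phase offsets `φ_i`. With the
default amplitudes the rate spans [0, 1] and peaks at `r ≡ φ_i` (mod
lattice). The amplitude parameter `A = 2/9` is the *per-plane-wave*
amplitude; this is the reading under which the closed-form conformal scale
below matches the numerically measured metric tensor exactly (describing
`A` as the peak firing rate would be off by the 3 summed waves plus the
baseline). All cells of a module share `f` and orientation; the phases are
the module's only free parameter and live on the hexagonal torus — the
Wigner–Seitz hexagon of the firing-field lattice (lattice constant
`2/(√3 f)`, circumradius `R = 2/(3f)`) with opposite edges identified.

A square-pattern comparator uses two orthogonal waves and a baseline of
`2A` (the baseline only shifts rates; all metric quantities depend on
gradients alone). A 1-D comparator, `s_i(r) = cos(2πr + iπ/N)`, maps a line
interval to an isotropic ring of radius `√(N/2)`.

## Geometry on the hexagonal torus

Wrapping maps a point to its lattice translate nearest the origin; boundary
ties are broken toward the lexicographically smallest candidate so that
wrapping is a function and idempotent. The shortest torus distance takes
the minimum Euclidean distance over the wrapped point and its six
neighbour-cell translates; the torus diameter equals the circumradius.
Quasi-uniform meshes come from a square grid on `[0, 3R/2)²` read in the
60°-rhombus basis, mapped back with the inverse change-of-basis matrix and
wrapped — the shear is area-preserving, so coverage is uniform. Uniform
sampling rejects from the minimum enclosing square (acceptance `3√3/8`).

## Conformal isometry

The population map `r ↦ g(r)` pulls the Euclidean metric of rate space back
to the plane through `G(r) = J(r)ᵀJ(r)` with `J_ia = ∂g_i/∂r_a` in closed
form. A module represents space as a *conformal isometry* when
`G(r) = σI`: local displacements in any direction map to neural
displacements scaled by the single factor `√σ`. Averaged over the unit
cell, cross-wave terms integrate to zero exactly, giving the closed-form
scale

    σ_hexagon = 3π²A²N f²,    σ_square = 2π²A²N f²,

a ratio of 3/2 at matched amplitude and cell count — the printed formula
corresponds to `f = 1`; the implementation exposes `f` and the scale grows
as `f²`. Notably the *mean* metric is isotropic and phase-independent; only
its spatial fluctuations depend on the phases, which is what the training
loss penalises:

    L = E_r [ (G_xx−σ)² + (G_yy−σ)² + 2G_xy² ],

estimated each step by Monte-Carlo over a fresh uniform mini-batch (default
256 positions). The scale-free conformal isometry score

    CIS = Var(G_xx) + Var(G_yy) + E[(G_xx−G_yy)²] + 2E[G_xy²]

uses plain sample moments (denominator n) and needs no σ. A generalised
loss replaces `σI` with an arbitrary SPD target metric field; because
phases cannot change the (isotropic) mean metric, representing anisotropic
targets additionally trains a 2×2 linear deformation of the wave vectors
(`k_j ↦ Mᵀk_j`), whose optimum for a target `diag(σ, cσ)` stretches the
pattern by `√c` and makes the unit pattern's iso-rate contours eccentric.

## Optimisation

Training is plain Adam (β = 0.9/0.999, ε = 1e-8, learning rate 1e-3 unless
stated) on closed-form gradients; phases are re-wrapped into the unit cell
after each step and all runs are bit-reproducible given the seed. The
conformal scale σ is a trainable scalar initialised at its closed-form
value, so the scaling law is verified rather than assumed; the fitted σ of
converged modules matches `3π²A²N` to well below 1%. The deformation matrix
(when trained) uses central finite differences for its 4 entries — a cheap
and robust alternative to third-derivative closed forms. The linear
decoding objective jointly trains the phases and an `N×2` readout `W`
(initialised to `1/(2N)` throughout) to minimise the mean shortest-torus
distance between `Wᵀg(r)` and `r`; its subgradient follows the minimising
lattice translate.

Typical behaviour with default conditions: 7 cells drop from ~10¹ to below
1e-11 (machine-precision zero) within 3000 steps; fewer than 7 cells stall
orders of magnitude higher; 100 cells reach ~1e-7 within 500 steps; modules
of 7k cells (k ≤ 19) pass 1e-6 within 1500 steps. Optimised 7-cell phases
always recover the 7-colour-map geometry: one central phase and six at
radius `lattice_constant/√7 = 2/√21`, rotated `arctan(√3/9) ≈ 10.893°` from
the unit-cell vertex direction (folded to [0°, 30°]).

## Topology

Activity clouds are evaluated on a fixed hexagonal mesh (default
24² = 576 positions) or per-step mini-batches, reduced by greedy maxmin
subsampling (default 150 points), and fed to an in-package Vietoris–Rips
persistence engine (dimensions 0–2 over Z/2). The engine reduces the
anti-transposed boundary matrices — cohomological column order — with
clearing and lazy column sorting; the default distance threshold is the
enclosing radius, at which the complex becomes a cone, so all finite
H1/H2 features are recovered exactly. It is validated against a brute-force
full-boundary-matrix reduction on small clouds and against the circle's
closed-form barcode (H1 persistence → √3 for a dense unit circle).

A cloud is called toroidal when the second-largest H1 persistence exceeds
`gap_factor` (default 3) times the third-largest and the largest H2
persistence similarly dominates the second. The factor is a package
convention — the barcodes themselves are exposed — chosen so converged
optimised modules pass while random small modules do not; random-phase
modules start passing around 20 cells, consistent with the size usually
quoted for toroidal population topology.

The toroidal training objective rewards (negative squared persistence) the
top-2 H1 and top-1 H2 features and penalises all remaining finite ones.
Its subgradient flows through each feature's birth/death critical edges —
the vertex pairs realising those distances — and from the critical pairwise
activity distances into the phases via the analytic Jacobian; the
persistence diagram is recomputed every step. One property of this
objective matters for interpretation: with sparsely sampled clouds the many
small sampling-noise bars of a genuine torus outweigh its two 1-D features,
and the objective then prefers a *sphere-like* configuration (one dominant
2-D void, no 1-D features). The balance tips to the torus once clouds are
dense enough (empirically ≳ 200 maxmin points for 6 cells), so the 6-cell
toroidal optimisation uses denser evaluation clouds than the other
analyses. This is a genuine feature of squared-persistence objectives, not
an optimiser failure; the constructed 6-phase sublattice arrangement
(2×3 lattice coordinates) is verified to be a persistent torus directly.

Representational ambiguity is mapped by marking mesh positions whose
population vector lies within ε (default 1e-2) of a reference point's and
removing the connected neighbourhood of the reference (chains of marked
points within two mesh spacings). One or two cells leave ambiguous sets;
three generically-phased cells resolve them.

## Phase statistics

Ripley's K uses periodic edge correction by duplicating wrapped phases to
the six adjacent cells; `H = √(K/π) − ε` has zero mean under uniformity
(verified: K is unbiased against `πε²`, and the residual bias of the square
root is within the delta-method bound). The default radii are 20 evenly
spaced values up to, but excluding, the circumradius. The permutation test
pools two groups and redraws labels (default 1000 permutations — the
number is configurable; published analyses of this kind variously use a
few hundred), reporting the two-sided percentile of the observed mean
difference.

The phase KDE is a wrapped Gaussian with *absolute* bandwidth (the kernel
SD in length units), evaluated over phases duplicated to a double tiling
and normalised to unit integral within the cell; it is unit-tested against
`scipy.stats.gaussian_kde` on whitened data where the two bandwidth
conventions coincide. The grid score of a phase density evaluates the KDE
on a 127×127 map at the unit-cell pixel scale (2R/64), correlates its
central 64×64 window against the full map (valid-mode sliding Pearson,
yielding displacement coverage of the cell's enclosing square), masks an
annulus (inner radius = bandwidth, outer = circumradius) and contrasts
rotational correlations at 60/120/180° against 30/90/150°. The printed
recipe's two grid extents are mutually inconsistent with its pixel counts;
the implementation keeps the pixel counts (127 = 2·64 − 1, which is what
makes the valid-mode correlation a full autocorrelogram) and one shared
pixel size, and crops one row/column so zero displacement sits exactly on
the rotation centre. Including 180° in the "peak" group follows the recipe
as written and differs from conventional ratemap gridness. For ~100 phases
the score separates optimised from random arrangements at bandwidths
≳ 1/6 of the circumradius (where the kernel resolves the phase-lattice
spacing `lattice_constant/√N`); at much smaller bandwidths both patterns
score noisily.

Hexagon fitting for 7 phases takes the phase minimising the summed torus
distance to the rest as the centre, the mean centre-to-outer distance as
the radius, and the 60°-periodic circular mean of the outer bearings as the
angle, reported folded into [0°, 30°].

## Ratemap pipeline and the synthetic-data generator

The generator evaluates a ground-truth module at the bin centres of a
32×32 map over a `[0, 3]²` arena (≈ 2.6 grid periods at f = 1 — enough for
six autocorrelogram peaks), optionally adds i.i.d. Gaussian noise or
Poisson resampling and blanks a random fraction of bins as unvisited;
regeneration is bit-identical given parameters and seed. It emulates the
binned, smoothed ratemaps of a recorded module of cells sharing scale and
orientation. It does *not* emulate occupancy-dependent sampling noise,
head-direction conjunctivity, finite spike counts along real trajectories,
multi-module contamination, or arena-boundary pattern distortions — so
passing round-trip tests shows the pipeline's inference is correct, not
that real recordings will be as clean.

Processing fills unvisited bins from their nearest visited neighbour and
smooths with a periodic (wrap-mode) Gaussian kernel of SD 2 bins;
trajectory data is first mean-binned (`binned_statistic_2d`). Grid
statistics come from the full-lag sliding-Pearson autocorrelogram: the six
local maxima nearest the centre give spacing (median distance) and
orientation (60°-periodic circular mean of bearings, minus the 30° offset
between lattice axes and pattern frame, folded to [0°, 60°)); the grid
score is the classic annulus rotation contrast `min(r₆₀, r₁₂₀) −
max(r₃₀, r₉₀, r₁₅₀)` with the 0.4 acceptance threshold. A cell's phase is
its ratemap peak nearest the arena centre, wrapped into the unit cell
defined by the module-median spacing and orientation — a deterministic
rule for a step published pipelines leave unspecified; noiseless round
trips recover phases within one bin. The finite-difference metric tensor
uses `np.gradient` (second-order central, one-sided at edges) and
population inner products of the gradient maps; it converges to the
analytic tensor at second order in the bin size, so comparisons exclude a
two-bin border where one-sided differences dominate. Baselines: per-cell
random circular shifts (phase shuffle), circular shifts aligning every
inferred phase to the arena centre (phase cluster), and one shared random
permutation of bins (space shuffle) — the last preserves the set of
population vectors while destroying exactly the spatial smoothness the
metric tensor probes. CIS values in cross-condition reports are normalised
by the squared mean diagonal metric so modules with different rate scales
are comparable.

## Problem sizes and determinism

Analyses default to the sizes above (3000-step / 256-batch CI fits,
576-point meshes, 150-point persistence subsamples, 100-trial CSR
ensembles, 12-model Ripley ensembles in the experiment registry); these are
the package's working scales and reproduce the qualitative and quantitative
claims. Heavier published-scale ensembles (50 models, 1500-step sweeps over
19 module sizes) are available through the same APIs. Every stochastic
routine takes an explicit seed and is bit-reproducible; persistence
subsampling, rejection sampling and permutation tests all draw from
`numpy.random.default_rng`.

## Known limitations

- The persistence engine is exact but quadratic-to-cubic in subsample size;
  clouds beyond ~250 points are slow on one core.
- The toroidal objective's sphere/torus preference depends on cloud density
  (above); the package defaults choose density per analysis accordingly.
- Ratemap orientation inference assumes a single coherent module; mixtures
  of modules would need clustering upstream.
- Real-data ingestion accepts pre-binned rate maps (NPZ); spike-train
  preprocessing is out of scope.
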