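# Methods

This note documents the models, estimators and numerical choices behind
`syntopo`, and what the synthetic benchmarks do and do not establish.

## Higher-order information measures

For a continuous random vector `X = (X_1, ..., X_N)` with differential
entropy `H`, the package works with four functionals (all in nats):

- total correlation `TC(X) = Σ_i H(X_i) − H(X)` — the total "collective
  constraint", zero iff the variables are jointly independent;
- dual total correlation `DTC(X) = H(X) − Σ_i H(X_i | X_−i)` — the
  information shared by two or more variables;
- O-information `O(X) = TC(X) − DTC(X)` — a signed balance: positive
  means redundancy-dominated, negative synergy-dominated;
- S-information `S(X) = TC(X) + DTC(X)`, and the normalized ratio
  `O/S ∈ [−1, 1]`, which makes systems with different total dependence
  comparable.

Expanding the conditional entropies gives the equivalent form
`O(X) = (N−2) H(X) + Σ_i [H(X_i) − H(X_−i)]`, which exposes O as an
*entropy combination*: a linear combination of the joint entropy and
marginal entropies whose dimension-weighted volume terms cancel. That
cancellation is what makes a low-bias k-nearest-neighbor estimator
possible.

## Nearest-neighbor estimation

All information quantities are estimated with a single kth-neighbor
search in the joint space (Chebyshev metric) followed by range counts
in the marginals, in the style of the Kraskov–Stögbauer–Grassberger
(KSG) algorithm 1 and its entropy-combination generalization. With
`ε(t)` the Chebyshev distance from sample `t` to its kth neighbor in
the joint space, `k_i(t)` the number of samples strictly within `ε(t)`
in marginal `X_i`, `k_−i(t)` the analogous count in the
(N−1)-dimensional marginal `X_−i`, and `F(m) = ψ(m) − ψ(n)`:

    TC^  = F(k) − Σ_i ⟨F(k_i(t) + 1)⟩_t
    DTC^ = (N−1) F(k) − Σ_i ⟨F(k_−i(t) + 1)⟩_t

with `O^ = TC^ − DTC^` and `S^ = TC^ + DTC^` holding *exactly* because
all four derive from the same counts. Searching once in the joint
space, instead of once per marginal, avoids stacking the
dimension-dependent biases of independent searches.

Parameters and conventions:

- `k = 4` by default (the customary KSG order; exposed everywhere);
- Chebyshev (max-norm) distances in joint and marginal spaces, chosen
  for consistency with the Rips filtration, which uses the same metric;
- strict range counts (`distance < ε(t)`) combined as `ψ(count + 1)`,
  the KSG algorithm-1 convention;
- natural logarithms throughout — every output is in nats;
- tie-breaking noise, uniform on `[−a, a)` with `a = 10⁻⁸` by default
  and seed-controlled, added to every coordinate before estimation.
  It is required for clouds with exactly duplicated values (the line
  benchmark has three identical columns) and harmless elsewhere; the
  screening pipeline disables it because its inputs are continuous;
- the normalized O-information is reported as missing (NaN) when
  `S < 10⁻⁶` nat, never coerced to zero: with no structured
  information, the redundancy/synergy balance is undefined.

A closed-form Gaussian oracle (`gaussian_o_information`) computes TC,
DTC, O and S from log-determinants of a covariance matrix and its
principal minors. It is used only for validation: on trivariate
Gaussian samples at n = 20,000 the estimator agrees with the closed
forms to well within 0.05 nat.

Performance: the 2D marginal counts use a compiled sorted-window scan
and the per-channel sorted orders and marginal structures are cached
across triads, so screening all 4,060 triads of a 30-parcel recording
(plus one circular-shift null each) takes a few minutes on one core.

## Benchmark shapes

Eight point-cloud families with known topology, 10,000 points each:
a line (`X1 = X2 = X3`), a plane, the unit sphere, the unit ball, the
surface and the solid interior of a torus (major radius 1, minor
radius 0.5), a trefoil knot, and a (5,3) torus knot. Sampling choices:

- sphere: normalized 3D Gaussian draws (exactly uniform); ball: uniform
  direction with radius scaled by `U^(1/3)`;
- torus surface: uniform in the toroidal and poloidal angles. Uniform
  angles slightly oversample the inner rim; an `area_correct` flag
  enables area-weighted rejection sampling, off by default because the
  information signal of interest is driven by the cavity, not by the
  mild density gradient;
- filled torus: uniform angles with cross-section radius scaled by
  `√U`;
- (p, q) torus knot: `q` toroidal and `p` poloidal windings on the same
  torus, uniform in the curve parameter;
- trefoil: the classic standalone curve
  `(sin t + 2 sin 2t, cos t − 2 cos 2t, −sin 3t)`, uniform in `t`.
  Scale is irrelevant to the information measures.

Rotation convention: "rotated by angle per axis" composes the
single-axis matrices as `R = Rx·Ry·Rz` and applies `R` to coordinate
columns, so the z-axis rotation acts first. Any fixed convention is an
isometry; one must be pinned down because O-information is
orientation-dependent, and this is the one under which the package's
benchmark table is defined. The rotated-plane/torus/knot suite uses
π/4 about each axis.

## PCA as rotation

`pca_rotate` centers a cloud and rotates it onto the eigenvectors of
its sample covariance — no whitening or scaling, so Euclidean
geometry (and hence topology) is untouched while the loading onto the
coordinate axes changes. Determinism: axes ordered by decreasing
eigenvalue, ties broken by input-axis order, each axis oriented so its
largest-magnitude loading is positive. Information that survives this
re-embedding is *intrinsic*; information that vanishes (the line's
redundancy, the plane's synergy) was *contextual* — a property of how
the cloud sat in the embedding space.

Caveat: when two eigenvalues nearly coincide (e.g. the trefoil's two
in-plane directions), the principal frame within that eigenspace is
determined by sample noise, and post-PCA information values for such
shapes are reproducible only given the seed, not across samplers.

## Vietoris–Rips persistence

`vr_diagram` computes persistent homology of the Rips filtration of a
distance matrix up to dimension 2 over Z/2, so the
"three-dimensional cavities" (dim-2 classes) of an embedded cloud are
fully resolved; simplices up to dimension 3 enter the reduction. The
engine is a persistent-cohomology matrix reduction with clearing,
implicit coboundaries and lazy heap columns — the optimization family
of modern Rips codes — compiled with numba. The filtration orders
simplices by diameter with ties broken by dimension and then by
combinatorial index; the diagram, as a multiset of (dim, birth, death)
values, is independent of the within-diameter tie-break.

Numerical/structural choices:

- default truncation at the *enclosing radius* (min over points of the
  max distance to any other point). At that value some vertex is
  within range of every other, the complex becomes a cone and hence
  contractible, so all classes in dimension ≥ 1 are already dead: the
  truncated diagram equals the full one at much lower cost. Explicitly
  smaller thresholds leave truncated classes open (death = ∞);
- zero-persistence bars are kept in the diagram (the test oracle
  compares diagrams bar-for-bar) but excluded from all summaries: a
  "void" must exist over a positive range of scales;
- infinite bars never enter average or maximum persistence;
- a guard refuses `maxdim=2` beyond 400 points unless forced — the
  simplex count grows as n⁴ and large clouds should be subsampled
  (`subsample_rows`, seed-deterministic, drawn uniformly without
  replacement).

The dim-2 summary (`tda_summary`) reports the void count, the mean
lifetime and the maximum lifetime. Correctness is anchored two ways:
hand-reduced diagrams (a unit square has one dim-1 bar √2 → 2; the
octahedron boundary has one dim-2 bar √2 → 2) and bar-for-bar equality
with an independent, unoptimized boundary-matrix reduction on random
clouds.

## Synthetic multi-scan series and planted triads

The screening pipeline is exercised on synthetic data with known
ground truth rather than on archival fMRI. The generator emulates the
statistical skeleton that matters for the null test:

- every channel is a stationary AR(1) process, re-initialized at scan
  boundaries (scans are independent recordings), z-scored per scan.
  The default lag-1 coefficient is 0.8, typical of band-passed BOLD at
  sub-second repetition times; AR(1) is the minimal model of the
  autocorrelation that the circular-shift null preserves;
- a redundant triad shares a common AR(1) latent: channel =
  `c·latent + √(1−c²)·idiosyncratic`, with coupling `c = 0.9` for the
  benchmark configuration (strong synchrony);
- a synergistic triad is a collider: two AR(1) parents and a child
  equal to their standardized sum plus observation noise. The sum (not
  a product) keeps the construction Gaussian, so the closed-form
  oracle certifies the sign of the planted O-information. The
  benchmark configuration uses noise 0.5: with moderate noise the
  synergistic cloud is only weakly compressible (PC1 share ≈ 60%
  versus ≈ 87% for the redundant construction and ≈ 33% for noise),
  mirroring the observation that synergy-dominated triads look nearly
  unstructured to variance-based methods;
- planted triads must be disjoint, so that every non-planted triad is
  genuinely null — overlapping constructions would make nominally null
  triads truly redundant and poison the false-positive accounting.

The benchmark screening configuration plants 5 redundant and 5
synergistic triads among 30 parcels (4 scans × 1,100 frames), screens
all 4,060 triads at 3 null standard deviations, and then computes the
topological features of the classified triads on a shared 150-frame
subsample (within the engine's comfortable range; the subsampled
frames are identical across triads so the features are comparable).

What passing these tests shows: the estimator, null, classifier and
feature pipeline jointly recover planted higher-order structure of
both signs against realistic autocorrelation, with few false alarms,
and reproduce the qualitative association between synergy, cavities
and incompressibility. What it does not show: anything about
hemodynamics, preprocessing artifacts, spatial structure, or effect
sizes in real recordings — real BOLD interactions are weaker and far
from the planted two-class idealization.

## Circular-shift null and classification

For a triad at channel positions (0, 1, 2), position `c` is circularly
shifted by `c × scan_length` frames. Each channel's marginal
distribution and autocorrelation are exactly preserved (the shift is a
circular permutation), but the three channels now originate from
different scans, so any surviving O-information is attributable to
autocorrelation alone. One null value per triad is pooled into a
single distribution (mean, SD); a triad is significantly redundant
(synergistic) when its raw O lies more than 3 SD above (below) the
null mean. The offsets are deterministic so results are reproducible;
`build_null` accepts any triad list, and the 3-SD multiplier is a
parameter. No multiple-comparison correction is applied beyond the
3-SD rule; the pooled-null design follows the screening procedure the
package implements end to end.

## Problem sizes and runtime

Defaults are sized for a single core: shape suite at n = 10,000 (a few
seconds per shape including PCA re-estimation), screening at 30
parcels × 4,400 frames (minutes), dim-2 persistence on 150-point
subsamples (seconds per cloud). The estimator scales as the KD-tree
search (n log n) and the persistence engine roughly as the number of
triangles below the enclosing radius (n³ worst case), which is why
triad TDA runs on subsamples rather than full 4,400-frame clouds.

## Known limitations

- The KNN estimator has a small negative bias on strongly dependent
  data and its printed-value agreement degrades for near-deterministic
  clouds (the line value depends on the tie-noise amplitude relative
  to point spacing).
- Post-PCA values for shapes with degenerate covariance spectra are
  sampler-dependent (see above).
- The persistence engine targets n ≲ 400 at dim 2; it is exact but not
  competitive with specialized C++ codes at larger sizes.
- The synthetic generator makes Gaussian, stationary, two-class
  assumptions; it is a test harness, not a BOLD simulator.
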