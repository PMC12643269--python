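# syntopo

Higher-order interactions in multivariate data can be described two
ways that rarely talk to each other: *multivariate information theory*
(is a triad of variables redundancy- or synergy-dominated?) and
*topological data analysis* (does the embedded point cloud contain
cavities?). `syntopo` implements both toolchains over a common
currency — an `(n, 3)` point cloud with Chebyshev geometry — so the two
notions of "higher-order structure" can be compared head to head, on
benchmark manifolds with known topology and on multi-scan time series
with planted interactions. It is aimed at researchers in systems and
network neuroscience, and complex-systems practitioners generally, who
want a self-contained, dependency-light reference implementation.

## What it computes

**O-information by nearest neighbors.** For `X = (X_1, ..., X_N)`,
with total correlation `TC = Σ H(X_i) − H(X)` and dual total
correlation `DTC = H(X) − Σ H(X_i|X_−i)`,

```
O(X) = TC(X) − DTC(X)        O > 0: redundancy-dominated
S(X) = TC(X) + DTC(X)        O < 0: synergy-dominated
```

estimated from a *single* kth-nearest-neighbor search in the joint
space plus marginal range counts combined through digamma terms (the
KSG / entropy-combination scheme; k = 4, Chebyshev metric, nats).
Closed-form Gaussian oracles are included for validation.

**Rips persistence of 3D cavities.** A from-scratch, numba-compiled
Vietoris–Rips persistent-homology engine (persistent cohomology with
clearing and lazy heap columns, Z/2 coefficients) computes diagrams up
to homology dimension 2 from a Chebyshev distance matrix, plus the
dim-2 summaries: number of voids, average and maximum persistence.

**The two studies.**
1. *Shape suite*: O-information of a line, plane, sphere, ball, hollow
   and filled torus, trefoil and (5,3) torus knot, before and after
   PCA rotation — separating intrinsic higher-order information
   (survives any rotation: the sphere's cavity, the knot's knottedness)
   from contextual information (an artifact of orientation).
2. *Triad screen*: for a multi-scan recording, estimate O for every
   triad of channels, test it against an autocorrelation-preserving
   circular-shift null (each channel shifted to a different scan),
   label triads beyond ±3 null SD, and correlate information features
   with topological features and PC1 variance share across classified
   triads. A synthetic BOLD-like generator with planted redundant
   (shared latent) and synergistic (collider) triads provides ground
   truth.

## Worked example

```python
from syntopo import ShapeSpec, generate_shape, estimate_all, pca_rotate
from syntopo import chebyshev_distances, vr_diagram, tda_summary
import math

q = math.pi / 4
sphere = generate_shape(ShapeSpec(kind="sphere", n=10_000, seed=1))
est = estimate_all(sphere, k=4)
print(f"sphere O = {est.o:+.3f} nat")          # sphere O = -1.375 nat
est2 = estimate_all(pca_rotate(sphere).rotated, k=4)
print(f"after PCA = {est2.o:+.3f} nat")        # after PCA = -1.376 nat

from syntopo import subsample_rows
sub = subsample_rows(sphere, 150, seed=0)
summ = tda_summary(vr_diagram(chebyshev_distances(sub)))
print(summ.n_voids, round(summ.max_persistence, 2))   # 3 0.64
```

The sphere is synergy-dominated (negative O) and PCA cannot change
that: the synergy is *intrinsic*, carried by the enclosed cavity that
the persistence summary detects as a dominant dim-2 void (lifetime
0.64, an order of magnitude above the sampling-noise voids).

Running the whole suite (`syntopo.run_shape_suite(seed=1)`) prints:

```
shape         o_raw    o_after_pca
line         +7.704     +0.000
plane        -2.823     -0.000
sphere       -1.378     -1.381
ball         -0.048     -0.056
torus_hollow -1.531     -1.103
torus_filled -0.348     -0.066
trefoil      +3.001     +2.771
knot_5_3     +1.964     +1.461
```

Read it by rows: the line's huge redundancy and the plane's synergy
are purely contextual (PCA kills them); the hollow shapes keep
negative O after PCA while their filled counterparts drop to roughly
zero (cavities carry intrinsic synergy); the knots keep positive O
(knottedness carries intrinsic redundancy).

A command-line interface mirrors the library:

```
syntopo shapes --kind sphere --n 10000 --seed 1 --out cloud.tsv
syntopo info --in cloud.tsv --k 4 --json info.json
syntopo tda --in cloud.tsv --subsample 150 --out diagram.tsv --summary s.json
syntopo synth --config spec.json --out bold.csv --truth truth.json
syntopo screen --bold bold.csv --scan-length 1100 --n-scans 4 --out triads.tsv
```

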