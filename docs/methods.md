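# Methods

## State space and moves

The simulation state is a closed self-avoiding unit-step polygon on the
simple cubic lattice Z³ (`bfacf.polygon.LatticePolygon`): cyclically
consecutive vertices differ by one axis-aligned unit step, all vertices are
distinct, and the length n (edges = vertices) is even with n ≥ 4. One BFACF
proposal picks an edge uniformly among the n edges and one of the 4 lattice
directions perpendicular to it, then pushes the edge one step that way.
Writing a, b for the edge endpoints and a′ = a+u, b′ = b+u for their
images, the proposal is classified by local geometry:

* a′ and b′ are the chain neighbors of a and b → **−2 move** (the hairpin
  a′–a–b–b′ is retracted; feasible when n ≥ 6);
* exactly one of them is the corresponding chain neighbor → **0 move**
  (corner flip; feasible when the target site is empty and admissible);
* neither → **+2 move** (a′, b′ are spliced in between; feasible when both
  sites are empty and admissible).

A "step" throughout the package is one proposal, accepted or not — the
only countable unit of the dynamics. The ergodicity classes of this move
set are the knot types, so knot conservation is structural; it is also
verified by invariant checks (below). Confinement is evaluated on vertex
positions only: edges between admissible vertices of a convex region
cannot leave it by more than half a step.

## Acceptance regimes

**Equilibrium (fugacity z).** Metropolis–Hastings targeting
π(ω) ∝ z^|ω| over polygons. A specific +2 transition is proposed with
probability 1/(4n) while its unique inverse −2 is proposed with
probability 1/(4(n+2)), so the acceptance probabilities carry the
length-dependent proposal correction

    A(+2) = min(1, z²·n/(n+2)),   A(−2) = min(1, z⁻²·n/(n−2)),   A(0) = 1.

The implementation is validated against an exact-enumeration oracle: all
self-avoiding polygons fitting a 2×3×3 box are enumerated by brute force
(8 078 of them) and the chain's empirical length-class frequencies in that
box are required to match P(n) ∝ C(n)·z^n within three cross-chain
standard errors. The fugacity is validated against the Z³ critical value
z₀ ≈ 0.2134 (= 1/μ, μ the self-avoiding-polygon connective constant);
confined runs remain well defined for any z ≤ z₀. Unconfined runs are
technically performed in a very large re-centering box (the simulation
grid), which is immaterial at the short equilibrium lengths used.

**Annealing (raw triplet).** Every feasible proposal of class Δ is
accepted with probability p(Δ) from the triplet [p(−2), p(0), p(+2)]; the
residual mass 1 − Σp is the stay-put probability. Because feasibility is
strongly asymmetric in a sphere with free volume (+2 needs empty sites,
−2 needs hairpins), any triplet with appreciable p(+2) grows the polygon.
A globule run stops at the first proposal after which n ≥ target length
(4000 by default), so final lengths are exactly the target. If the
proposal budget is exhausted first, the run fails loudly with the length
reached — the signature of a triplet that cannot fill the sphere.

The default protocol is: randomize the knot's reference embedding with
10⁵ equilibrium proposals at z = 0.1 (configurable; the full-fidelity
profile uses 10⁷), translate its centroid to the confinement center, and
anneal inside a sphere of radius 10.5 lattice units (4 945 sites; a
4000-edge globule occupies 81% of them). The sphere radius, target length,
triplet, randomization length and replicate count are all exposed in the
configuration; the stated defaults are the study conditions. The
alternative stop criterion sometimes quoted for this protocol — occupying
96% of the lattice sites within a radius-11 sphere — is numerically
inconsistent with a radius-10.5 sphere at 4000 edges (5 575 × 0.96 ≈ 5 352
sites) and is not implemented; the fill fraction is logged instead.

## Knot seeds

Reference embeddings (`bfacf.seeds`) are frozen integer coordinate lists:
the 4-step square (0₁), a 24-edge trefoil at the known lattice minimum,
and near-minimal 5₁ (34), 5₂ (36) and 9₁ (54) embeddings. They were
obtained by latticizing smooth parametric curves (torus-knot curves; for
5₂ the closure of the 6-letter braid word σ₁²σ₂²σ₁σ₂⁻¹, whose crossing
number bound of 6 together with determinant 7 pins the knot type) and
shrinking them with fixed-topology BFACF. Near-minimality is sufficient:
randomization erases seed geometry, so only the certified knot class
matters.

Connected sums (3₁)ⁿ are built by chaining copies of a 24-edge trefoil
motif that carries two straight 2-edge junction runs; consecutive copies
share a junction run and the shared runs are deleted from the union,
merging the chain into one polygon of 20n + 4 edges (asymptotically 20
steps, i.e. 0.5% of a 4000-edge globule, per summand). Each summand
occupies its own slab and meets the rest of the curve only at its
junctions, so the result is the n-fold connected sum; determinants 3ⁿ are
verified exactly for n up to 40. A `folded` layout additionally inserts
16-edge *unknotted* elbow cycles (connected sum with the unknot changes
nothing) to pack the chain into a bounding box growing like n^(1/3); the
merge verifier checks every placement voxel-exactly, and folded layouts
are certified against the line layout at small n.

Large composite seeds do not fit the confining sphere as built. They are
funneled in by grow/shrink cycles under a *soft radial bias*: proposals
that would move material outward beyond the target radius have their
acceptance multiplied by a factor annealed from 0.25 to 0 as the polygon
approaches the sphere, while everything (including material still outside)
stays mobile. Growth to 1.5× the current length provides the slack the
chain needs to rearrange; low-fugacity shrinkage removes it again. All
moves are ordinary BFACF moves, so the knot class is conserved throughout.
A hard ratcheting wall was tried first and stalls near 115% of the target
radius — dozens of boundary contacts must retreat simultaneously — which
is why the soft bias exists. The funneled template is computed once per
ensemble and each replicate then re-randomizes it *inside* the sphere with
its own stream before annealing; replicates therefore share the template's
deep history, which makes the bootstrap spread of composite ensembles an
underestimate of true protocol-level dispersion (see Limitations).

## Knot certification

The invariant is the Alexander determinant |Δ(−1)|, which separates every
knot type used here (1, 3, 5, 7, 9, 3ⁿ). The polygon is projected along an
integer direction; genericity (no coincident projected vertices, no
non-transverse or triple intersections, no folded-back adjacent edges) is
checked exactly in integer arithmetic, and degenerate directions are
replaced from a deterministic perturbation schedule — coordinates are
never perturbed. Crossings are extracted with exact rational arithmetic;
at t = −1 the Wirtinger relation at a crossing is sign-independent
(x_in + x_out − 2·x_over = 0), so the determinant is |det| of any
(c−1)×(c−1) minor of that integer matrix. Minors up to 64×64 use
fraction-free Bareiss elimination over Python integers; larger ones use
Gaussian elimination modulo ~30-bit primes (numba-compiled) recombined by
CRT under a Hadamard bound, so values like 3⁴⁰ ≈ 1.2·10¹⁹ are exact.
Long polygons are first shortened by fixed-topology BFACF shrinkage
(which cannot change the class) to keep diagrams small; certification
tries several generic directions and requires them to agree.

## Observables

For every unordered vertex pair at cyclic arc distance s ≥ 2, a contact is
scored 1 at Euclidean distance 1 and w at √2 (default w = 1/√2, exposed as
a parameter; doubling it moves ensemble slopes by less than the bootstrap
SE, which the suite asserts). P(s) is the summed weight at s divided by
the vertex count n — not a probability normalization, but constant factors
cancel in the log-log slope. R(s) is the plain mean Euclidean distance
over the pairs at arc distance s; R(1) = 1 exactly. Chain neighbors
(s = 1) are excluded from contacts; the fit window makes this immaterial.
Both curves are validated against a naive O(n²) double-loop oracle.

Ensemble curves are pointwise means over equal-length conformations.
Slopes are ordinary least squares of log₁₀(value) on log₁₀(s) over integer
s ∈ [9, 55] (the same window is used for R(s), configurable). Two
uncertainties are reported: the OLS standard error on the averaged curve,
and a seeded bootstrap over conformations (default 1000 resamples);
comparisons against reference values use the bootstrap.

## Knot localization (excision)

A cut pair is two vertices at Euclidean distance 1 with arc distance ≥ 3;
an excision replaces one of the two arcs between them with the direct unit
edge (by default the longer arc is removed) and is accepted iff the
certified determinant is unchanged. The stochastic greedy search draws cut
pairs uniformly at random, restarts from the original polygon several
times, and reports the shortest knot-preserving polygon found. The core
length is monotonically non-increasing within a restart, the cross-restart
minimum is non-increasing in the number of restarts, and the core can
never undercut the knot's minimal lattice length. On 300-edge trefoil
globules the cores come out near a quarter of the total length — the knot
is delocalized, consistent with the large-scale behavior reported for
full-size globules; the published minima (1012 edges for 3₁ at full scale)
are minima over 10⁴-conformation ensembles and are not reproducible as
point values at desk scale.

## Scales, seeds and determinism

Desk-scale replicate counts are used throughout: 56 conformations per
primary ensemble in the test suite, 120 in the acceptance script (30 for
the 100-trefoil composite), versus 10⁴ at full fidelity. At these counts
the ensemble-slope standard error is roughly 7× the full-scale one, and
slope comparisons are made within three such reduced-scale SEs (or the
bootstrap SE when it is larger). Randomization uses 10⁵ proposals per
replicate by default; 10⁷ is a config switch away but changes desk-scale
slopes by less than their noise. All randomness flows from integer seeds
through a splitmix-style stream splitter (`derive_seed`) into a
xorshift64* generator inside the compiled kernel, so ensembles are
bit-reproducible for a given base seed regardless of execution order, and
(config, seed) maps to an identical output tree (asserted at smoke scale).

## Design choices and limitations

* **Proposal bookkeeping.** Edge uniform among n, direction uniform among
  4; other published BFACF variants differ here, which is why equilibrium
  correctness is pinned behaviorally by the enumeration oracle rather than
  by quoting acceptance constants.
* **Composite slopes saturate.** For (3₁)ⁿ the contact slope degrades
  with n as expected (−1.077 at n = 20, ≈ −0.95 at n = 40), but in this
  implementation it saturates around −0.87…−0.96 for n = 60…100 instead of
  continuing to ≈ −0.56 as reported at full scale. Six protocol variants
  (longer randomization, unconfined annealing, overfilling the sphere to
  96% and shrinking back, extended grow/shrink mixing) all land in the
  same range, so the difference is structural rather than statistical; it
  most likely traces to the undocumented expansion/initialization step of
  the original protocol (see the radius-11/96% inconsistency above). The
  computed value is reported as-is, and the n = 60 vs n = 100 ordering is
  not resolvable at desk scale — the ordering tests assert only the
  clearly separated pairs.
* **Determinant-only certification.** |Δ(−1)| cannot distinguish mirror
  images or every knot pair in general, but it separates the supported
  set; chirality is not tracked.
* **Shared funnel template.** Composite replicates are independent only
  downstream of the funneled template, so their bootstrap SE understates
  protocol-level dispersion; primary-knot ensembles have fully independent
  replicates.
* **p(0) = 0.40 regime.** The slope shift at high p(0) is reproduced in
  direction but is milder here (≈ −1.04 versus −0.974 at full scale); like
  the composite saturation this appears sensitive to initialization
  details the protocol leaves open.
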