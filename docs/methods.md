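# Methods

## The registration problem

Given a fixed *reference* image and a moving *float* image, intensity-based
registration searches for the geometric transform that best aligns the
float to the reference. `tpsreg` restricts itself to 2D rigid+scale
transforms, parameterized as `(x, y, θ, Z)`:

* `x` — translation along the vertical axis, pixels, positive **up**
  (toward row 0);
* `y` — translation along the horizontal axis, pixels, positive **left**
  (toward column 0);
* `θ` — rotation, degrees, positive counterclockwise;
* `Z` — isotropic scale about the image center, `Z > 0`.

This axis convention (up/left positive) is deliberate and used everywhere,
including ground-truth inverses; it differs from the usual (col, row)
image convention. The forward transform composes **scale about the center,
then rotate about the center, then translate**; the rotation/scale center
is the geometric image center `((H−1)/2, (W−1)/2)`. Given that composition
the exact inverse is `Z' = 1/Z`, `θ' = −θ`, `t' = −R(−θ) t / Z`, which is
what `TransformParams.inverse()` returns and what the benchmark uses as
ground truth.

Resampling uses inverse mapping with bilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1). Destination pixels whose
source coordinate leaves the input domain receive fill value 0 and a
False entry in a validity mask that travels with every image. Rotation
matrix entries within 1e-12 of {−1, 0, 1} are snapped, so quarter-turn
rotations and integer translations are exact index permutations
(bit-equal to `np.rot90`/slicing), which pins the sign and axis
conventions down in tests.

## The similarity metric

The objective is mutual information between the binned intensities of the
reference and the resampled float:

    MI(A, B) = Σ_{a,b} p(a,b) · log2[ p(a,b) / (p(a) p(b)) ]

with `p` estimated from a joint histogram of `B × B` equal-width bins on
[0, 1] (default `B = 64`; the last bin is right-closed). Only pixels valid
in *both* images contribute, so the out-of-overlap fill never produces a
spurious background–background MI bonus. The logarithm base is 2 (MI in
bits); any base would rescale the objective without moving its argmax.
Marginals are computed from integer count sums and the final sum uses
`math.fsum`, making MI exactly invariant under histogram transposition.
Zero-probability terms are skipped and tiny negative rounding residue is
clamped to 0. A float moved fully out of frame has no joint overlap; the
similarity function scores that configuration 0 (the worst possible
value) rather than raising, so optimizers can move back in-frame.

## The tissue-P-system optimizer

The optimizer organizes a swarm as a fixed three-level membrane tree: one
level-1 *output membrane*, three level-2 membranes, and nine level-3 leaf
membranes (13 in total), connected by bidirectional channels between every
parent–child pair and every sibling pair. Only the nine leaves hold
particles; level 2 and the output membrane aggregate.

Each system step applies, in order:

1. **Evolution (leaves).** Every particle's velocity is updated with
   three attractors — the membrane's local best, a neighbor best chosen
   uniformly at random among the sibling bests received last step, and
   the parent's best:

       v ← ω(t)·v + l0·z0·(local − p) + l1·z1·(nbr − p) + l2·z2·(par − p)
       p ← p + v

   with `z0, z1, z2 ~ U(0,1)` drawn independently per particle *and per
   dimension*, velocities clamped per dimension, positions clipped into
   bounds. The membrane's local best is then the objective argmax over
   the new positions and the incumbent, ties keeping the incumbent.
2. **Intra-level communication.** Each leaf's neighbor list is replaced
   by value-copies of its two siblings' local bests (replicative: sources
   are never mutated; each step overwrites the list with the freshest
   information).
3. **Inter-level communication.** Each level-2 membrane pools value-copies
   of its three children's bests; each child receives a copy of the
   parent's current best.
4. **Selection/substitution.** Each level-2 membrane max-substitutes its
   local best over the pooled candidates (ties keep the incumbent).
5. **Promotion.** The output membrane max-substitutes over the three
   level-2 bests.

The system halts after exactly `T` steps; the output membrane's object is
the answer. Because every selection is a max-substitution, each
membrane's best score and the global best are non-decreasing, and the
particle count (9·m) and topology are invariant. The entire run is a pure
function of (objective, config, seed): one `numpy.random.Generator`
threaded in a fixed membrane order drives every draw.

Defaults (units in parentheses): `m = 10` particles per membrane (90
total), `T = 40` steps, `l0 = l1 = l2 = 1.4` (dimensionless; splitting a
conventional total social weight near 4 across the three attractors),
inertia `ω` decaying linearly 0.9 → 0.4 over the run, velocity clamp half
the bound width per dimension, positions initialized uniformly in bounds
with zero velocities, search box ±15 px / ±15° / Z ∈ [2/3, 1.5]. Before
the first communication a leaf's neighbor and parent attractors fall back
to its own local best, making step 1 well defined. Degenerate (fixed)
dimensions are expressed as `lo == hi` bounds — the clamp collapses to 0
and the dimension stays pinned, which is how the benchmark fixes `Z = 1`
when scale is known.

## Baselines

* **PSO** — one flat swarm (default 30 × 60 iterations), textbook
  inertia + cognitive + social update (`c1 = c2 = 2`), same clamping and
  clipping contracts.
* **GA** — real-coded, tournament selection (k = 3), BLX-0.5 blend
  crossover (rate 0.9), Gaussian mutation (rate 0.1, σ = 0.1 × bound
  width), elitism of 1.
* **PSO+Powell** — PSO followed by derivative-free coordinate-direction
  refinement: bounded scalar line maximization (Brent) along each axis,
  sweeps until a full sweep improves less than `tol = 1e-4` or 20 sweeps.
  Only improvements are accepted; `tol = ∞` disables refinement and
  returns the PSO result unchanged.

In the benchmark harness, evaluation budgets are matched by default: each
baseline's iteration/generation count is scaled so its total
objective-evaluation count equals the tissue-P-system run's
(9·m·(T+1) = 3690 at defaults). The Powell polish consumes additional
line-search evaluations beyond the matched budget; that surplus is a
documented property of the hybrid, not an attempt at fairness.

## Synthetic phantoms

The phantom is a nested-ellipse head slice: an elliptical head outline,
a gray-matter rim, a white-matter interior whose center is offset by a
few pixels, and a V-shaped pair of ventricle-like CSF cavities with
opposite tilts. The offset and the opposing tilts remove 180° rotational
symmetry so the rotation angle is identifiable. Per-class base
intensities plus seeded Gaussian noise (default σ = 0.01, clipped to
[0, 1]) give a four-level image whose 64-bin MI is well above zero at
alignment. The T1-like/T2-like pair reuses one label map with different
per-class lookups and independent noise; CSF is dark (0.12) in T1-like
and bright (0.90) in T2-like, the inverted contrast that makes the pair
multimodal. Default size is 128×128 so an 8-repetition, 4-algorithm
benchmark completes at desk scale.

What the phantom does **not** emulate: anatomical detail, bias fields,
partial-volume effects, or acquisition noise statistics. Passing the
recovery benchmark therefore demonstrates the optimizer and metric
machinery, not clinical-grade registration accuracy on real MRI.

## Benchmark protocol and statistics

Each experiment builds a float image from the reference by a known
forward transform — the standard constructions are (x=8, y=6, θ=5°, Z=1)
and the same with Z=0.8 — and registers it back with each algorithm over
8 repetitions seeded `base_seed + r`, so any single run can be reproduced
in isolation. Recorded per run: the absolute deviation of each recovered
parameter from the ground-truth inverse (angles compared modulo 360°) and
the final MI. The summary reports Max, Min, Mean and Δ per algorithm and
quantity, where **Δ is the half-range (Max − Min)/2** — the spread
statistic used throughout. The harness enforces Min ≤ Mean ≤ Max and
Δ ≥ 0 on its own outputs by construction.

Note the scale bookkeeping: a float built by shrinking to Z = 0.8 has
ground-truth inverse scale 1/0.8 = 1.25, and the reported |ΔZ| deviation
is measured against that inverse under the documented forward
composition.

## Observed comparative behavior (computed by the tests and the
acceptance script, not assumed)

On the 128×128 phantom with translation+rotation only (scale pinned),
all four optimizers recover the transform to well under a pixel and a
degree; at matched budgets the flat PSO, which spends its budget on ~3×
more iterations than the membrane system's 40 steps, polishes the final
answer slightly finer and can edge the membrane optimizer's mean MI by a
fraction of a percent. When scale is unknown (the 4-D search), the flat
swarm's run-to-run spread grows by two orders of magnitude while the
membrane optimizer stays tight and ahead on mean MI — the hierarchical
restarts earn their keep on the harder landscape. The comparative
acceptance test asserts the membrane-vs-PSO mean-MI inequality on the
primary (3-D) benchmark; under these study conditions that clause can
fail even though the method dominates on the harder problems, and it is
left to report honestly rather than being re-scoped to a friendlier
construction.

## Numerical choices and edge cases

* Ties in every max-selection keep the incumbent, which stabilizes the
  monotone trace and makes tie behavior testable.
* A constant reference image has zero entropy, hence MI ≡ 0; runs on it
  complete and return score 0.
* Images are min-max normalized to [0, 1] per image at load time; a
  constant image normalizes to all zeros.
* Interpolation loss: the forward-then-inverse round trip reproduces a
  band-limited image to ~2e-3 per pixel (tolerance 1e-2 in tests);
  white-noise images lose much more under any interpolating resampler,
  which is a property of bilinear smoothing, not of the transform.
* Problem sizes in the test suite (64×64 phantoms for rule-level tests,
  128×128 for the recovery benchmark, 8 repetitions, reduced
  particle/step counts for structural tests) are chosen so the full suite
  represents the method at desk scale.

## Known limitations

* 2D only; no deformable or gradient-based registration.
* The MI estimator is the plain binned plug-in estimator; no kernel or
  Parzen smoothing, so the objective is piecewise-constant at the
  sub-bin level and optimizers rely on interpolation smoothing for
  sub-pixel precision.
* Baseline hyperparameters are reasonable defaults, not tuned favorites;
  the GA in particular is a strong elitist blend-crossover variant and
  should not be read as a straw man.
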