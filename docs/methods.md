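# Methods

## Model

The segmentation target is modeled as a star-shaped object around a
user-supplied seed point: every ray from the seed crosses the object
boundary exactly once. The surface is represented discretely by one
boundary index `k_r ∈ [0, Z−1]` per ray, rays being the `R` surface
points of an icosphere (subdivided icosahedron, `R = 10·4^n + 2` at
level `n`). Node `(r, z)` sits at `seed + (z+1)·δ·d_r`; the seed itself
is deliberately not a node, which avoids a degenerate zero-radius node
shared by all rays.

A surface is feasible iff `|k_r − k_r′| ≤ Δ_r` for every pair of rays
adjacent in the icosphere triangulation. Its cost is
`Σ_r c(r, k_r)` with `c(r, z) = |I(r, z) − μ|`, the absolute deviation
of the trilinearly interpolated intensity from the object's mean gray
value `μ`, estimated as the mean of a voxel cube around the seed. The
minimizer over all feasible surfaces is found exactly by reduction to a
minimum-cost closed set: telescoped terminal weights
(`w = c` at `z = 0`, `w = c(z) − c(z−1)` above) make the closed set's
terminal weight equal its envelope's cost, and the optimal closed set is
the source side of an s-t min-cut. Among equal-cost optima the
*maximal* closed set is returned (a node is retained unless the sink is
still reachable from it through unsaturated arcs), so on cost plateaus —
homogeneous interiors — the boundary lands on the outermost optimal
layer, the object's full extent.

Assumptions worth spelling out: the object is star-shaped about the
seed; its interior intensity is roughly homogeneous and well summarized
by the seed-region mean; the boundary lies within the ray reach
`Z·δ`; and a boundary is *present* as an intensity deviation — the cost
model knows nothing about gradients or texture.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `subdivision_level` | 3 (642 rays) | – | angular resolution of the surface |
| `n_samples` (Z) | 60 | – | radial nodes per ray |
| `step_mm` (δ) | min voxel spacing | mm | radial node spacing; reach = `Z·δ` |
| `delta_r` (Δ_r) | 2 | layers | max boundary-index jump between adjacent rays; 0 = sphere |
| `mean_radius_voxels` | 3 | voxels | half-width of the seed cube for `μ` |

Defaults target prostate-scale objects in ~1 mm MR volumes: 642 rays
resolve a 3–5 cm organ to a few degrees, 60 × 1 mm of reach covers any
plausible central gland from an interior seed, and Δ_r = 2 allows mild
ellipticity without letting single rays chase noise. All are exposed in
the API and CLI.

## Numerical choices

* **Min-cut backend.** `scipy.sparse.csgraph.maximum_flow`, which works
  on 32-bit integer capacities. Float weights are embedded by fixed-point
  scaling chosen so the weight-magnitude sum lands at 2^28; the total-cost
  quantization error is then ≲ 4·10⁻⁹ of that sum. The reported
  `total_cost` is recomputed in floats from the returned boundary, so
  rounding can at most flip choices between surfaces closer in cost than
  the quantization — far below meaningful image contrast. "Infinite"
  capacities are a finite BIG = (sum of all finite capacities) + 1,
  which can never saturate.
* **Tie-breaking** is the maximal minimum closed set, computed by
  reverse reachability from the sink in the residual graph.
* **Out-of-bounds samples** cost `1 + max(in-bounds intensity range,
  max in-bounds cost)` — strictly above any attainable in-bounds cost,
  keeping the surface inside the volume without infinities.
* **Base arcs** `s → (r, 0)` with BIG capacity force the innermost layer
  into the closed set; without them the empty set would be a trivial
  optimum. This encodes the assumption that the seed is inside the
  object.
* **Inter-ray arcs** at `z < Δ_r` clamp their target to layer 0, keeping
  the base layer closed.
* **Voxelization** uses the star-shape property directly: a voxel center
  at distance ρ from the seed, in direction u, is inside iff
  `ρ ≤ s(u)`, with `s(u)` the barycentric interpolation of the three
  incident cut radii `(k_r+1)·δ` over the icosphere triangle containing
  u. For the surfaces this graph can produce the radial test is exact;
  triangle lookup goes through the nearest template vertex with a
  global fallback, ties on edges resolving to the lowest triangle index.
* **Exhaustive oracle.** `brute_force_surface` is a depth-first search
  over per-ray boundary indices with interval constraint propagation
  (assigning `k_r` bounds every ray `r′` to `k_r ± dist(r, r′)·Δ_r`) and
  admissible bound pruning; it explores every assignment not provably
  dominated, so it is exact, and it shares no code with the min-cut
  path. A size guard rejects instances whose constrained search space
  exceeds ~10⁹ states; the vacuous case `Δ_r ≥ Z−1` short-circuits to
  per-ray minima.

## Phantoms: what they test and what they don't

`make_phantom` produces hard-edged two-intensity spheres/ellipsoids with
seeded i.i.d. Gaussian noise and an exact truth mask. Default study
conditions used throughout the tests: 64³ voxels at 1 mm, 15 mm radius,
foreground 150, background 50 (contrast 100), noise sd 0 or 5. These
exercise geometry, graph optimality, reconstruction and metrics
end-to-end, but differ from clinical MR in known ways: no partial-volume
ramp at the boundary (a 1-voxel linear shell is available behind the
`partial_volume` flag, off by default), Gaussian rather than Rician
noise, no bias field, no anatomical texture. Passing phantom tests
therefore demonstrates the machinery is correct, not that clinical
accuracy matches the published ten-case figures, which required expert
seeds on real scans.

Two behaviors observed on phantoms are properties of the method, not
bugs:

* **Interior bias at hard edges.** Costs at the true boundary are ~half
  the contrast (interpolation mixes both sides), so the optimal surface
  rests at the outermost *clean interior* sample — about one radial step
  inside a hard edge. On the 15 mm/1 mm phantom the ceiling is ≈ 89 %
  Dice (measured 87.6 %, volume −21 %), because a 1 mm radial deficit on
  a 15 mm sphere costs ~19 % of the volume. Gradual real-world
  boundaries shrink this bias toward the gradient midpoint.
* **Weak localization in noisy homogeneous interiors.** The surface cost
  sums exactly one node per ray, so in a featureless interior it carries
  no radius preference; exact ties (which the maximal-set tie-break
  resolves outward) exist only in noise-free data. With noise, the
  optimum threads low-|noise| nodes and tends to settle near the seed,
  where interpolated samples are strongly correlated with the
  seed-region mean. The cut still never leaks into the high-cost
  background (100 % containment in the seeded repetitions); in the
  intended interactive use the operator repositions the seed when the
  result looks collapsed, and boundary contrast in real scans is what
  anchors the surface.

## Design decisions that were genuinely open

* The polyhedron is an icosphere (near-uniform ray density, stable
  deterministic indexing); the original description says only
  "polyhedron" and does not state `R`, `Z`, δ, Δ_r, or the
  mean-estimation neighborhood, so all are configurable with the
  defaults above.
* The surface radius convention places mesh vertices and the mask
  boundary *at* the outermost retained node, `(k_r+1)·δ` — the cut's
  boundary nodes are the surface. The alternative (boundary midway to
  the first removed node) would halve the interior bias on hard edges
  but overshoot on gradual ones.
* Dice of two empty masks is defined as 0 (with a warning); summary
  standard deviations use the sample convention (n−1), which is the
  convention that reproduces the published ten-case summary from its
  per-case column.
* Seeds may be given in world mm or 0-based voxel indices; internally
  everything is world mm, with voxel centers at
  `origin + direction·(spacing ∘ index)`.

## Problem sizes in the test suite

Unit and property tests run on the 12-ray icosahedron with `Z ≤ 6`
(oracle comparisons: 108 seeded instances), level-2/3 icospheres for
geometry and reconstruction, and 40³–64³ phantoms end-to-end; the whole
suite plus the acceptance script completes in well under a minute on one
CPU. The end-to-end default (642 rays × 30–60 samples, ≈ 150 k arcs)
solves in ≈ 0.4 s.
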