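# spherecut

Seed-based graph-cut segmentation of roughly spherical 3D objects in
medical image volumes — one click inside the object, one polynomial-time
min-cut, one closed surface.

The method was developed for delineating the prostate central gland in
T2-weighted MR scans, where a clinician marks a single seed point during
an intervention and needs the organ's boundary and volume within a
second. It applies to any blob-like structure whose interior intensity
is roughly homogeneous: tumors, adenomas, aneurysm sacs.

## Method

From a user seed point **p**, rays are cast through the `R` surface
points of a subdivided icosahedron, and each ray `r` is sampled at `Z`
radial positions, node `(r, z)` sitting at `p + (z+1)·δ·d_r`. Each node
costs

```
c(r, z) = | I(r, z) − μ |
```

where `I` is the trilinearly interpolated image intensity and `μ` is the
object's mean gray value, estimated from a voxel cube around the seed.
A directed graph on these nodes has two families of ∞-weighted arcs:

* `A_z`: `(r, z) → (r, z−1)` — any retained node drags all deeper nodes
  on its ray in, so the retained set is a solid star-shaped region;
* `A_r`: `(r, z) → (r′, max(0, z−Δ_r))` for rays adjacent in the
  icosphere triangulation — neighboring boundary indices may differ by
  at most `Δ_r` (`Δ_r = 0` forces a sphere).

Terminal arcs carry the telescoped weights `w(r, 0) = c(r, 0)`,
`w(r, z) = c(r, z) − c(r, z−1)`; their prefix sums recover `c`, so the
minimum-cost *closed set* — found exactly by an s-t min-cut — has a
total terminal weight equal to `Σ_r c(r, k_r)`, the cost of its upper
envelope `k`. That envelope is the segmentation surface; it is turned
into a triangulated mesh (STL) and a voxel mask on the input grid, and
compared against references with the Dice Similarity Coefficient
`DSC = 2|A∩B| / (|A|+|B|)`.

No external data is needed: a phantom generator produces sphere and
ellipsoid volumes with analytically known ground truth.

## Worked example

Generate a noise-free phantom (15 mm sphere, foreground 150, background
50, in a 64³ grid at 1 mm), segment it from its center, and evaluate:

```sh
spherecut phantom --shape sphere --dims 64,64,64 --spacing 1,1,1 \
    --center 31.5,31.5,31.5 --radius 15 --fg 150 --bg 50 \
    --noise-sd 0 --rng-seed 42 --out vol.nrrd --out-truth truth.nrrd

spherecut segment --input vol.nrrd --seed 31.5,31.5,31.5 \
    --seed-space world --delta-r 1 --subdiv 3 --samples 30 --step 1 \
    --out-mask mask.nrrd --out-mesh surface.stl --report report.json

spherecut evaluate --pred mask.nrrd --ref truth.nrrd --report eval.json
```

which prints

```
INFO phantom written to vol.nrrd (14328 foreground voxels)
INFO cut cost 4.235e-12, mask 11176 voxels (11176.0 mm^3)
DSC 87.64 %  |  auto 11176.0 mm^3 (11176 vx)  ref 14328.0 mm^3 (14328 vx)
```

Reading the numbers: the cut cost is ~0 because every surface node sits
on zero-cost interior samples; the mask holds 11176 of the 14328 true
voxels. The shortfall is systematic, not noise: absolute-difference
costs are ~half the contrast *at* the boundary itself, so the optimal
surface rests at the outermost clean interior sample — one radial step
(here 1 mm, ≈ 87–89 % Dice on a hard-edged 15 mm sphere) inside the
true edge. On real MR data with gradual boundaries this bias shrinks
toward the gradient mid-point. See `docs/methods.md` for the full
parameter discussion.

The same pipeline is available from Python:

```python
import spherecut as sc

spec = sc.PhantomSpec("sphere", (64, 64, 64), (1, 1, 1), (31.5, 31.5, 31.5),
                      (15.0,), fg_intensity=150, bg_intensity=50, rng_seed=42)
volume, truth = sc.make_phantom(spec)
result = sc.segment(volume, sc.SeedPoint((31.5, 31.5, 31.5)),
                    sc.SegmentationConfig(delta_r=1, n_samples=30, step_mm=1.0))
print(sc.dice(result.mask, truth))   # 87.64...
```

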