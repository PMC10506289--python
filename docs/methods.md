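# Methods

## Model and geometry

A rigid pose θ = (rx, ry, rz, tx, ty, tz) acts on the implant surface as an
intrinsic Z-Y-X Euler rotation (degrees) about the mesh centroid followed by
a translation (mm). Rotating about the centroid decouples rotational from
translational pose error in the reported per-DOF statistics; the inverse
pose under this convention is (Euler of Rᵀ, −t).

Each view is a point-source perspective camera. Defaults: source 1000 mm
from the isocenter, detector 200 mm behind it and perpendicular to the
principal ray, 0.2 mm/px, 512×512 images, view azimuths 45° and 135° about
the vertical axis (a 0°/90° frontal-lateral rig is equally supported). The
world origin projects to the image center of both views. These numbers are
typical of biplanar radiographic rigs; nothing in the method depends on them
beyond the field of view (≈ 85 mm at the isocenter) comfortably containing
the component.

Silhouettes are produced by rasterizing the perspective-projected triangles
into a binary raster (for a watertight, consistently wound surface only the
front-facing triangles are rasterized — they cover the full silhouette and
the union is hole-free), keeping the largest connected blob, and tracing the
outer boundary into an ordered, counter-clockwise pixel chain
(Moore-neighbor tracing). Contour tangents are central differences two
pixels apart along the chain. The rasterizer, blob cleanup and tracer are
numba kernels: one cost evaluation projects the mesh twice and must run in
about a millisecond inside the optimizer loop.

## Pre-processing

Contour branch: global 256-bin histogram equalization → 3×3 median → 
non-local means (7×7 patches, 21×21 search window, strength 0.8 × the
estimated noise σ) → Canny with Gaussian σ = 1.4 and hysteresis thresholds
0.1 / 0.2 of the maximum gradient magnitude. Edge tangents are the gradient
rotated 90°.

Label branch: SLIC superpixels on the raw greyscale image lifted to Lab as
L = 100 × intensity, a = b = 0. Defaults K = 200, compactness m = 0.3, 10
iterations, connectivity enforced. Two parameter notes:

- *Compactness.* scikit-image normalizes the spatial term differently from
  the classic SLIC weight; with L on [0, 100], m = 0.3 is the regime where
  superpixel boundaries adhere to the implant contour. At the textbook
  m = 10 the partition degenerates to a near-regular grid that ignores the
  boundary, and the object-specificity cost stops depending on pose.
- *K.* Superpixel size trades off the region cost's dynamic range (large
  cells, small K) against its smoothness (small cells, large K); K = 200 on
  512×512 balances the two.

## Cost terms and their calibration

The edge potential field is Φ = exp(−ρ d) with d the exact Euclidean
distance to the nearest edge pixel (distance transform with feature
propagation, so the directional term reuses the same nearest-edge
assignment). The default ρ = 0.005 px⁻¹ makes Φ's reach ≈ 200 px ≈ 15 mm at
the isocenter: the edge term is then a smooth, nearly monotone funnel over
the entire ±10° / ±10 mm initial-error range, which is what a sampling-based
optimizer needs to find the basin at all. Sharper fields (ρ ≳ 0.02) localize
more aggressively but create strong distractor minima on bone edges — the
classical failure of pure contour matching.

The object-specificity cost is the exact label-counting formula: per-label
totals are precomputed once; only the interior label histogram depends on
the pose (one `bincount` over the silhouette window per view). Its landscape
is the complement of the edge term's: a deep, sharp crater within ~1–2 mm of
the true pose (superpixel boundaries snap to the implant contour, so exact
alignment zeroes the label leakage), a high rim at 2–6 mm where the interior
boundary splits every boundary superpixel maximally, and a *lower* plateau
far away where the displaced interior misses the component entirely and only
pays generic grid-splitting costs — a label fully swallowed by the interior
is free under the formula, whatever it looks like.

The weight β = 10 matches the two terms' dynamic ranges (E spans ≈ 0.8 over
the search box, V ≈ 0.04): large enough that the region crater sharpens the
optimum and vetoes edge-aligned false poses, small enough that the region
rim cannot wall off the edge term's funnel mid-search. β and ρ are config
keys (`similarity.beta`, `similarity.rho`) meant to be swept when the
imaging conditions change.

Candidate poses whose projection leaves an image (or whose contour is >50%
outside) receive a finite penalty cost of +10 rather than raising, so the
search remains bounded near the detector edge.

## Optimizer

Exploration-Selection over a per-axis 2¹⁰-level discretization of the
bounded search box (±15° / ±15 mm around the initial pose). Per iteration,
every individual takes one unconditional random move — with probability 0.9
a single-axis step of log-uniform length 1..256 levels, with probability 0.1
a uniform redraw inside the box — then random pairs fight and the loser
becomes a copy of the winner; the best-ever solution is re-inserted over the
current worst, so the best fitness never increases. Non-finite costs reject
the move. The run is a fixed budget (population 20 × 800 iterations ≈ 16 k
evaluations, reference settings) with an optional stagnation exit, and is
bit-reproducible from its seed.

The long-range exploration edges are load-bearing: without them the
population concentrates within a few iterations and, from a ±10° / ±10 mm
start, never samples the optimum's basin within the budget (verified by
instrumenting a run: 0 of 16 k evaluations within 6 mm of the truth).

## Synthetic ground truth

Phantoms are watertight assemblies of trimesh primitives, ~50 mm across,
with a per-seed ±3% scale jitter:

- *femoral-like* — two unequal capped-cylinder condyle rolls bridged by a
  block. Cylinders, not spheres: two spheres would leave the rotation about
  their line of centers silhouette-invariant, a degeneracy real condyles do
  not have. The unequal radii remove mirror symmetry (mirror IoU of the
  silhouette < 0.8).
- *tibial-like* — a flat tray with a central stem, nearly mirror-symmetric
  (mirror IoU > 0.9), carrying the symmetric-pose hazard that motivates
  biplanar acquisition.

Rendering: background 0.15 plus a smooth soft-tissue field (three wide
Gaussians, amplitudes 0.05–0.18) plus bone-like clutter — near-vertical
(±25°) elongated super-Gaussian ridges with flat cores and crisp flanks,
amplitudes 0.3–0.6, half of them biased to cross the component — then the
component silhouette overwritten at 0.95 (metal saturates the detector), and
i.i.d. Gaussian noise (default σ = 0.05), clipped to [0, 1]. The vertical
shaft orientation mirrors knee radiographs, where femoral and tibial/fibular
cortices are the long edges competing with the implant contour. Scenes
regenerate bit-identically from their seeds.

What the generator does *not* emulate: Beer–Lambert attenuation and scatter
(intensities are compositing, not physics), detector blur and glare,
anatomy-shaped bones (shafts are ridges, with no condylar flares or
trabecular texture), patient-specific implant geometry, and calibration
error (the rig is known exactly). Passing accuracy numbers therefore
demonstrate the method's behavior under controlled, idealized-calibration
conditions, not clinical performance.

Experiment protocol: per trial, a scene is generated (one mesh per kind by
default, re-posed per trial), the true pose is drawn within ±5° / ±5 mm of
the isocenter pose, the initial pose adds a uniform ±10° / ±10 mm per-DOF
perturbation (≈ 12 mm mean initial vertex RMSE), and each similarity mode is
registered from the same initial pose and seed. Errors are vertex RMSE
between poses and per-DOF absolute errors (rotations wrapped to [0°, 180°]);
modes are compared by an unpaired two-sample Z-test on per-trial RMSE with
unpooled variances. All per-trial seeds derive from one master seed, so any
trial reproduces in isolation.

## Numerical choices

- Pixel centers at integer coordinates; contour pixels snapped to the grid
  for field lookups; out-of-image contour pixels contribute Φ = 0 but count
  in the normalizer.
- Exact Euclidean distance transform (scipy) with argmin propagation; ties
  broken by scan order.
- Triangle rasterization uses inclusive edge tests so shared edges never
  leave seams; degenerate (zero-area) projected triangles are skipped.
- Equal-fitness candidates do not replace the incumbent best (strict
  improvement), so exact cost ties cannot cause drift from the optimum.
- Constant images pass through histogram equalization unchanged; an empty
  edge map is an error (the potential field is undefined), while an empty
  projected interior is an error for the region term.

## Problem sizes used by the shipped experiments

The test suite and the acceptance script run the protocol at 6 scenes
(3 per kind) with the reference optimizer settings (20 × 800), which is the
scale one CPU covers in minutes; the statistics are means over 6 trials
rather than the 64 of a full study, and single-trial failures therefore move
the means visibly.

## Known limitations

- The object-specificity similarity *alone* is not reliably optimizable on
  these scenes from ±10° / ±10 mm starts: its crater-rim-plateau landscape
  repels sampling-based search (the plateau outside the rim is cheaper than
  the rim, so tournament selection discards candidates that approach the
  crater). In this package it functions as the precision term of the hybrid
  cost; used alone it converges only when the start or a lucky sample is
  already near the truth. Both readings of the ambiguous p_h definition
  (share of interior vs share of label) were implemented and show the same
  pathology; the share-of-interior reading is kept.
- With the smooth default field (ρ = 0.005), the edge-only mode is more
  stable than classical sharp chamfer-style matching, so the measured gap
  between hybrid and edge-only modes is smaller than under sharp-field
  conditions; the hybrid mode remains the most accurate and is the only one
  that both finds and sharpens the optimum across all tested scenes.
- Euler angles near gimbal lock (ry → ±90°) are not re-parameterized; the
  search bounds (±15°) keep the protocol far from it.
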