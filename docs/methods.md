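# Methods

This note documents the models, conventions, parameters, and numerical
choices behind `mvgraph`, what the synthetic phantoms do and do not emulate,
and the known limitations of the approach.

## Coordinate and intensity conventions

Volumes are numpy arrays indexed `(z, y, x)` with a physical voxel size in
μm per axis in the same order; the physical position of a voxel is
`index × voxel_size` with 0-based indices, and z is depth below the first
slice. Raw detector intensities live on the 10-bit scale 0–1023 signal
units (SU); `normalize_intensity` divides by 1023. The reference acquisition
grid is 0.99 μm laterally with a 2.64 μm z-step, resampled to isotropic
0.99 μm before analysis.

## Phantoms

`generate_phantom` rasterizes tubes (cubic-spline centerlines with a radius
profile), beads, and spherical somas into two channels. Rasterization is
binary — a voxel is foreground iff its center lies within the local radius
of the centerline — with no sub-voxel antialiasing, so the exported ground
truth (centerline vertices at ≤1.73 μm spacing with true radii per time
point, and the junction/endpoint graph) is exact. Edge softness comes from
the PSF stage, not the rasterizer. Centerline distance is evaluated against
a dense polyline sampled at ≤0.25 μm, so the rasterization error is below a
quarter voxel.

Per-time-point radius modulation is a scalar multiplier per tube; a
non-uniform radius along a vessel is expressed through the per-control-point
radius profile.

**PSF.** When no measured kernel is supplied, the default is an anisotropic
Gaussian with FWHM 0.99 μm lateral and 2.64 μm axial, matching the nominal
resolutions of the resonant-scanner acquisition regime the package targets.

**Noise and SNR.** SNR is defined as mean foreground intensity divided by
the standard deviation of background intensity (the foreground mask is the
ground-truth rasterization for phantoms). This definition is a package
convention — acquisitions report an SNR without defining the statistic — and
it is what the noise calibrator inverts: given a target SNR, the Gaussian
sigma is solved by bisection on the measured SNR of the clipped output, with
one fixed noise field, to within 2%. Noise is added after PSF convolution
for acquisition emulation; the validation experiments inject noise at the
points their protocols specify instead (see below).

**Background level.** The default background is 150 SU. The noise levels
that the SNR regimes of interest imply (background SD ≈ 85–125 SU) remain
approximately Gaussian after clipping to the 10-bit range only if the
background sits well above zero, as it does in acquisitions where the
detector offset keeps the background off the floor. With a near-zero
background the calibrated noise becomes strongly clipped and asymmetric
between lumen and background, which biases any gradient-based boundary
detector inward; the offset keeps the phantom noise statistics faithful to
the regime the detector is designed for.

## Preprocessing

- **Upsampling** preserves physical extent: the output voxel count per axis
  is `round(extent/target) + 1`; intensities are trilinear, masks
  nearest-neighbor.
- **Registration** minimizes mean squared error on images smoothed with a
  2-voxel Gaussian, initializing the translation by sub-voxel phase
  cross-correlation and refining the full rigid pose (rotation about the
  volume center + translation) with Powell descent; rotation parameters are
  carried in degrees so optimizer steps are commensurate with the μm
  translation axes. The estimate is deterministic. On phantoms it recovers
  prescribed shifts within 0.5 voxel and rotations up to 10° within 0.5°.
  The transform maps reference-frame points into the moving image's space;
  resampling pulls moving intensities back onto the reference grid (edge
  values extended for images, hard zero for masks).
- **Mask cleanup**: background components (6-connectivity) that do not touch
  the volume boundary and whose entire 26-neighborhood is vessel are filled;
  vessel components (26-connectivity) under 50 voxels are removed. The
  6/26 duality avoids topological paradoxes. The operation is idempotent.
- **Union across time points**: each registered mask is dilated three times
  with a radius-1 disk applied slicewise in xy (a 3D ball is available as an
  option), then OR-ed. This bridges transient capillary gaps from
  red-blood-cell plugs at single time points.
- **Evaluation metrics**: Dice, precision, recall, HD95 and mean surface
  distance; surfaces are foreground voxels with a background 6-neighbor,
  distances Euclidean in μm between boundary voxel centers, HD95 the larger
  of the two directed 95th percentiles, and the mean surface distance the
  sum of both directed distance sets divided by the total boundary count.

## Graph extraction

Skeletonization uses homotopy-preserving 3D thinning. Parallel thinning can
annihilate perfectly even-width, perfectly symmetric objects (a lab-bench
phantom case, not an imaging one); the implementation detects an empty
result, re-thins at doubled resolution and maps the centerline back.

Hairs — terminal segments shorter than 20 μm of polyline arc length — are
removed iteratively, shortest first (ties broken by lexicographic voxel
order), rebuilding the graph after every removal. When a junction carrying
two terminal branches loses the shorter one, its degree falls to 2 and the
longer branch merges with the continuing vessel, which can lift it over the
hair threshold — this greedy order minimizes the centerline length removed.
Self-loops shorter than the threshold are removed the same way. Isolated
segments (terminal at both ends) are vessels, not hairs. After a removal,
voxels whose skeleton neighbors remain mutually connected without them are
collapsed, and degree-2 pass-through node clusters are dissolved by merging
their incident edges, so nodes are exactly branch points and endpoints.
Pure cycles get an anchor node at their lexicographically smallest voxel and
become one self-edge.

Vertex paths are smoothed per edge with a Gaussian in vertex-index units
(σ = 3); the path is linearly extrapolated by 4σ samples at both ends before
filtering so straight lines are exact fixed points of the smoother. Tangents
are normalized `np.gradient` central differences of the smoothed path,
one-sided at endpoints.

## Radius estimation

The vessel-wise prior is the mean of the Euclidean distance transform over
the mask voxels assigned (by nearest centerline vertex) to each edge. For an
ideal cylinder of radius R this average is R/3 (+ about half a voxel of
discretization), so the prior is a *kernel-scale parameter*, not an unbiased
radius; every smoothing sigma is 0.8 × prior and the spoke length is
4 × prior (at least 10 μm, capped at the plane). An alternative prior that
averages the distance transform along the centerline (≈R) is available as
`over="centerline"`.

Deconvolution is Richardson–Lucy with multiplicative updates starting from
the input image (so zero iterations return the input unchanged and the
output is non-negative); the default iteration count is 10, exposed as
configuration.

Orthogonal planes are sampled at 0.99 μm with trilinear interpolation on a
basis completing the tangent to a right-handed frame, seeded by the
coordinate axis least aligned with the tangent; radius estimates are
invariant to the in-plane roll by the rotational symmetry of the spoke fan
(verified to within 5% on beads). Out-of-volume samples are filled with the
volume's median intensity and counted; vertices whose plane is more than 25%
filled are marked missing.

Boundary detection per plane: 2D Gaussian smoothing (σ = 0.8 × prior) only
for finding the lumen center — the local intensity maximum nearest the plane
center within 10 px; profiles are then sampled from the unsmoothed plane
along 36 spokes at 10° steps, at 1/5 of the grid spacing with bicubic
interpolation, smoothed with a 1D Gaussian (σ = 0.8 × prior), and
differentiated. The wall is the global minimum of the signed radial
gradient, searched outward with ties resolved toward the center (a bright
lumen on a dark background makes the steepest descent mark the wall;
center-proximal tie-breaking avoids capturing neighbors). Boundaries further
than 2 SD from the 36-spoke mean are flagged; the vertex radius is the mean
of retained distances, and a vertex with more than half its spokes flagged
is unreliable and raises. Failed vertices are recorded as missing, never
fatal; an edge with no usable vertex is flagged.

Neuron distances are the distance transform of the neuron mask sampled at
the vertex, minus the vertex's mean radius, clipped at zero; an empty neuron
mask yields infinity.

## Validation experiments

Three self-contained experiments probe the boundary detector. The problem
sizes below are the package defaults and what the acceptance suite runs.

1. **Rescaling** (scale recovery): cross-section planes are built from
   straight, slightly tilted tubes of radii 1.5, 2.19, 3, 4.5, 6 μm —
   2.19 μm being the mean capillary radius regime — blurred, degraded to
   SNR 6.9, deconvolved, and baseline-estimated; 5000 simulations each
   resample one plane by a factor U(0.5, 2) with bicubic interpolation and
   re-estimate. The kernel prior is multiplied by the factor, the only
   choice consistent with scale equivariance (resampling a plane by s must
   multiply the estimate by s, which holds within 2% noiseless). The report
   is the R² of the post-rescale estimate against factor × baseline.
2. **Noise injection** (robustness): Gaussian noise with σ ~ U(0, 500) SU is
   added to the extracted plane after deconvolution but before the
   detector's smoothing; the percent radius change against baseline is
   recorded. Estimates are stable (median |Δ| < 3%) up to 200 SU and degrade
   several-fold beyond 300 SU.
3. **Beads** (absolute accuracy and averaging): 289 spheres with certified
   diameters N(7.32, 0.27²) μm are rasterized with sub-voxel random center
   jitter, blurred, Richardson–Lucy deconvolved, then degraded with white
   Gaussian noise added after deconvolution — the bead degradation protocol
   — with a single sigma calibrated once on a nominal-diameter reference
   bead to measured SNR 5.05. Each bead is segmented with a fixed midpoint
   threshold (Otsu is degenerate when the object occupies well under 1% of
   the volume: it splits the background mode), its centroid taken from the
   mask, and its diameter estimated as twice the mean retained boundary
   distance pooled over random orthogonal planes at four averaging levels
   (1×3, 2×4, 4×12, 10×36 planes × spokes). Beads touching the volume edge
   are excluded and reported.

At the default conditions the bead experiment recovers the certified
diameter to within ≈7% at the highest averaging level with the estimate SD
falling strictly with averaging (≈0.46 → 0.26 μm from 1×3 to 10×36 at one
seed). Two systematic effects are worth knowing. First, the
gradient-minimum detector carries a sphere-specific inward bias of a few
percent — a sphere's cross-section interior is dome-shaped rather than flat,
which pulls the steepest descent inward, and noise deepens the effect —
that cylindrical vessels do not show (tube radii recover within ≈5% at
SNR 6.9 across 1.5–6 μm). Second, synthetic beads are cleaner than real
ones: without surface irregularity, aberrations, or focus error, the
single-plane, 3-spoke estimator scatters noticeably less than it does on
acquired bead images, so the low-averaging SD is smaller than an
experimental value even though the averaging trend and the high-averaging SD
reproduce. Both effects are consequences of simulating ideal geometry, and
they bound what passing phantom tests can claim about acquired data.

## Network metrics

- `delta_radius` is the post-stimulus mean of the edge's mean radius minus
  the baseline mean; the baseline SD is across baseline time points. The
  responder gate is strict (`> 2σ`), and vessels of length ≤ 20 μm — too few
  cross-sections for a trustworthy average — are never responders. A vessel
  with one baseline time point has undefined SD and is excluded with a
  warning.
- The assortativity population defaults to capillary segments (mean baseline
  radius < 5 μm) with a defined radius change, responders and non-responders
  alike; the statistic is the Pearson correlation with every undirected link
  contributing both orientations, matching the standard numeric
  assortativity, and a zero-variance population raises rather than reporting
  a silent 0.
- Resistance uses the edge's mean vertex radius at the time point (edge-wise
  rather than vertex-wise series summation, for stability; the vertex-wise
  sum is a straightforward variant). Units are SI (1 cP = 1e-3 Pa·s; lengths
  μm → m), with a 1 PΩ ≡ 1e15 Pa·s·m⁻³ display convention on
  `EfficiencyResult.value_per_peta_ohm`.
- Efficiency excludes vessels wider than 10 μm in diameter, takes junctions
  of the retained subgraph as nodes, least-resistive (Dijkstra) path
  resistances between all ordered pairs, and averages their inverses;
  disconnected pairs contribute zero inverse resistance (no flow path)
  rather than shrinking the node set. Comparisons across time points fix the
  node set of the baseline computation.

## Pipeline

`run_pipeline` chains the stages with explicit configuration (baseline/post
frame assignment is never inferred from filenames), logs per-stage records
into a manifest, writes GraphML/CSV/JSON artifacts, and tags stage failures
with the stage name after writing a partial manifest. Deterministic stages
are bit-reproducible for a fixed configuration; stochastic stages are
seeded. The end-to-end phantom demonstration (4 time points, 51×81×81
voxels, 3 vessels) runs in a few seconds; the validation experiments at full
size run in under a minute — sizes chosen so the whole suite iterates
quickly on a single CPU.

## Limitations

- Segmentation of in vivo data is out of scope by design; the threshold
  segmenter is adequate only for two-level phantoms and beads.
- Phantom noise is additive white Gaussian; photon shot noise, line
  artifacts of resonant scanning, depth-dependent attenuation, and motion
  are not modeled.
- The hair-merge rule implements one reading of iterative shortest-first
  pruning with junction re-evaluation; other readings exist and are isolated
  behind the `prune_hairs` contract.
- The distance-transform prior is a biased radius scale; all kernel sizes
  are calibrated to it, so swapping in the centerline prior changes detector
  smoothing and should be revalidated on phantoms.
- Efficiency is a geometric proxy for flow (fixed viscosity, no boundary
  conditions, no hematocrit effects); it parallels mean transit time but is
  not a hemodynamic simulation.
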