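# mvgraph

Graph reconstruction and sub-voxel radius estimation for 3D cerebral
microvascular networks imaged with volumetric two-photon fluorescence
microscopy (2PFM).

## The problem

Functional hyperemia — the local adjustment of blood flow to neuronal
activity — is coordinated across *networks* of hundreds of interconnected
microvessels, not just individual capillaries. Quantifying that coordination
requires (1) reconstructing the vascular network of a field of view as a
graph whose edges are vessel segments, (2) estimating each vessel's radius
at micrometer-spaced points along its centerline, at every time point of a
stimulation experiment, and (3) summarizing the geometric response at the
network level. `mvgraph` implements this analysis chain for two-channel
(vascular dye + neuron label) 3D volumes, plus a synthetic phantom generator
with exact ground truth so that every stage is testable without any acquired
data. Segmentation itself is pluggable: the pipeline consumes binary masks
from any segmentation model, and ships only a threshold segmenter for
phantoms and beads.

## What it computes

**Reconstruction.** Repeated acquisitions of one field of view are resampled
to an isotropic 0.99 μm grid, rigidly registered to the first baseline scan
(mean-squared-error metric), segmented, cleaned (enclosed background pockets
filled; components under 50 voxels removed), dilated three times with a
radius-1 disk, and unioned across time points so transient red-blood-cell
plugs do not sever capillaries. The union mask is thinned to a one-voxel
centerline; terminal "hair" branches shorter than 20 μm are pruned
iteratively, shortest first; branch points become nodes and centerline
chains become edges with vertices every 0.99–1.71 μm.

**Radius estimation.** At every vertex, the Richardson–Lucy-deconvolved
image is sampled in the plane orthogonal to the local centerline tangent
(tangents from Gaussian-smoothed vertex coordinates, σ = 3 vertices). From
the lumen-center intensity maximum, 36 radial spokes (10° apart, 5× bicubic
upsampled) carry 1D intensity profiles, smoothed with a Gaussian whose sigma
is 80% of a vessel-wise distance-transform prior; the wall is placed at the
minimum of each profile's gradient, boundaries further than 2 SD from the
36-spoke mean are rejected, and the vertex radius is the mean of the
retained boundary distances. Vertex-to-nearest-neuron distances are computed
from the neuron-mask distance transform with the vessel radius subtracted.

**Network analysis.** Per-vessel summaries (baseline radius, baseline SD
across repeated scans, stimulus-induced change Δr) feed:

- *responder classification* — a vessel longer than 20 μm dilates
  (constricts) if Δr > 2σ_baseline (Δr < −2σ_baseline);
- *assortativity* q — the Pearson correlation of Δr across pairs of vessels
  that share a junction (each undirected link counted in both orientations),
  q ∈ [−1, 1];
- *hydraulic efficiency* E of the capillary bed — with Poiseuille resistance
  ρ = 8μL/(πR⁴) per segment (μ = 4 cP; vessels wider than 10 μm in diameter
  excluded), E = ⟨1/ρ_ij⟩ over all ordered junction pairs, where ρ_ij is the
  least-resistive path resistance and disconnected pairs contribute 0;
- Table-style morphometrics (segment, junction and neuron counts and
  densities, length density in m/mm³, vascular volume density).

## Worked example

A Y-shaped phantom network with three baseline scans (±2% radius jitter) and
one post-stimulus scan in which one vessel dilates by 10%, imaged at the
vascular-channel SNR of resonant-scanner acquisitions (≈6.9):

```python
import numpy as np
from mvgraph import *

c = np.array([24.5, 39.5, 39.5])
tips = [c + np.array([20, 28, 5]), c + np.array([-18, -30, 12]),
        c + np.array([5, 8, -34])]
spec = PhantomSpec(
    volume_shape=(51, 81, 81),
    tubes=[TubeSpec(np.vstack([c, t]), r)
           for t, r in zip(tips, [3.0, 2.5, 2.0])],
    neurons=[SphereSpec(c + np.array([10, 25, 25]), 5.0, 500.0)],
    timepoints=[1.0, [1.02] * 3, [0.98] * 3, [1.10, 1.0, 1.0]],
)
truth = generate_phantom(spec)

psf = PSFModel.gaussian()
volumes = [apply_psf_and_noise(truth.volumes[t]["vascular"], psf,
                               target_snr=6.9, seed=100 + t,
                               foreground_mask=truth.masks[t]["vascular"])
           for t in range(4)]

config = PipelineConfig(vascular_paths=[], neuron_paths=[],
                        baseline_frames=[0, 1, 2], post_frames=[3],
                        output_dir="out/demo", register=False,
                        segmentation="fixed", fixed_threshold=375.0)
result = run_pipeline(config, volumes=volumes,
                      neuron_volumes=[truth.volumes[0]["neuron"]])

graph = result["graph"]
print(f"segments={graph.n_segments} junctions={graph.n_junctions} "
      f"endpoints={graph.n_endpoints}")
print(result["summaries"][["edge", "baseline_radius_mean", "delta_radius",
                           "responder"]].round(3).to_string(index=False))
rep = result["report"]
print(f"assortativity q = {rep['assortativity']:.3f}")
print(f"efficiency change = {rep['efficiency_pct_change']:+.1f}%")
```

prints

```
segments=3 junctions=1 endpoints=3
 edge  baseline_radius_mean  delta_radius responder
    0                 2.450         0.028      none
    1                 1.904         0.062      none
    2                 2.963         0.277   dilator
assortativity q = -0.500
efficiency change = +25.3%
```

The reconstructed topology equals the ground truth exactly; the vessel with
the prescribed ×1.10 modulation (true baseline radius 3.0 μm) is the only
responder, its Δr of +0.28 μm reading the prescribed +10% dilation off the
images; the single dilation among static neighbors makes the three-vessel
junction disassortative (q = −0.5); and the one widened capillary lowers
least-resistive path resistances enough to raise network efficiency by 25%.
Per-vertex radii, vessel summaries, the GraphML graph, and the JSON network
report are written to the output directory.

A command-line interface mirrors the library: `mvgraph phantom`, `mvgraph
preprocess register|upsample|clean|union|evaluate`, `mvgraph graph`,
`mvgraph validate rescale|noise|beads`, and `mvgraph run --config
config.yaml`.

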