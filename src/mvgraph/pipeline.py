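"""End-to-end orchestration: volumes in, network report out.

The pipeline chains upsampling, normalization, rigid registration to a
reference time point, (threshold) segmentation, mask cleanup, temporal
union, skeletonization, hair pruning, graph construction, tangent
estimation, Richardson–Lucy deconvolution, vertex-wise radius estimation,
neuron distances, vessel summaries, responder classification, and network
metrics.  The threshold segmenter exists so phantoms run end to end; real
acquisitions bring their own segmentation masks (segmentation models are
pluggable inputs, not part of this package).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from . import graphify, io, netmetrics, preprocess, radii
from .volume import BinaryMask, ImageVolume, PSFModel


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def threshold_segment(volume: ImageVolume, method: str = "otsu",
                      threshold: float | None = None) -> BinaryMask:
    """Binary segmentation by global threshold (phantom/bead use).

    ``method="otsu"`` picks the threshold from the intensity histogram and
    errors on constant images; ``method="fixed"`` uses ``threshold``.
    Deterministic.
    """
    vox = volume.voxels
    if method == "otsu":
        if vox.max() == vox.min():
            raise ValueError("Otsu undefined on a constant image")
        threshold = threshold_otsu(vox)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding needs a threshold")
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")
    label = "neuron" if volume.channel == "neuron" else "vessel"
    return BinaryMask(vox > threshold, volume.voxel_size, label=label)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, explicit and serializable.

    ``vascular_paths`` / ``neuron_paths`` list one file per time point (the
    neuron channel may list a single file).  Baseline/post frame indices
    are explicit, never inferred from filenames.
    """

    vascular_paths: list[str]
    neuron_paths: list[str]
    baseline_frames: list[int]
    post_frames: list[int]
    output_dir: str
    reference_frame: int = 0
    voxel_size: tuple | None = None
    target_spacing: float = 0.99
    segmentation: str = "otsu"
    fixed_threshold: float | None = None
    min_component_voxels: int = 50
    dilation_rounds: int = 3
    min_hair_length_um: float = 20.0
    smoothing_sigma_vertices: float = 3.0
    rl_iterations: int = 10
    capillary_max_radius_um: float = 5.0
    efficiency_max_diameter_um: float = 10.0
    viscosity_cp: float = 4.0
    register: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        b, p = set(self.baseline_frames), set(self.post_frames)
        if not b or not p or b & p:
            raise ValueError("baseline and post frames must be disjoint "
                             "and nonempty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**io.load_yaml(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, volumes=None, neuron_volumes=None) -> dict:
    """Execute the full reconstruction and analysis chain.

    ``volumes``/``neuron_volumes`` may be passed in-memory (lists of
    :class:`ImageVolume`, one per time point); otherwise they are loaded
    from the config's paths.  Artifacts (graph, vertex table, vessel
    summaries, network report, manifest) are written to the output
    directory; the returned dict holds them in memory too.  Stage failures
    raise :class:`PipelineError` after writing a partial-results manifest.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - tag and abort
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                io.save_report(manifest, out_dir / "manifest.json")
                raise PipelineError(name, str(exc)) from exc
            manifest["stages"][name] = {"status": "ok"}
            return result
        return deco

    @stage("load")
    def _load():
        if volumes is not None:
            vasc = list(volumes)
            neur = list(neuron_volumes) if neuron_volumes else []
        else:
            vasc = [io.load_volume(p, voxel_size=config.voxel_size)
                    for p in config.vascular_paths]
            neur = [io.load_volume(p, voxel_size=config.voxel_size,
                                   channel="neuron")
                    for p in config.neuron_paths]
        return vasc, neur
    vasc, neur = _load

    @stage("upsample")
    def _upsample():
        up = [preprocess.upsample_isotropic(v, config.target_spacing)
              for v in vasc]
        un = [preprocess.upsample_isotropic(v, config.target_spacing)
              for v in neur]
        return up, un
    vasc, neur = _upsample

    @stage("register")
    def _register():
        if not config.register or len(vasc) == 1:
            return vasc, [preprocess.RigidTransform.identity() for _ in vasc]
        ref = vasc[config.reference_frame]
        aligned, transforms = [], []
        for t, vol in enumerate(vasc):
            if t == config.reference_frame:
                aligned.append(vol)
                transforms.append(preprocess.RigidTransform.identity())
                continue
            tf = preprocess.rigid_register(vol, ref)
            aligned.append(preprocess.apply_transform(vol, tf))
            transforms.append(tf)
        return aligned, transforms
    vasc, transforms = _register
    manifest["stages"]["register"]["n_transforms"] = len(transforms)

    @stage("segment")
    def _segment():
        masks = [threshold_segment(v, config.segmentation,
                                   config.fixed_threshold) for v in vasc]
        masks = [preprocess.clean_mask(m, config.min_component_voxels)
                 for m in masks]
        if neur:
            nmask = threshold_segment(neur[config.reference_frame
                                           if len(neur) > 1 else 0],
                                      config.segmentation,
                                      config.fixed_threshold)
        else:
            nmask = BinaryMask(np.zeros(vasc[0].shape, bool),
                               vasc[0].voxel_size, label="neuron")
        return masks, nmask
    masks, neuron_mask = _segment

    @stage("union")
    def _union():
        return preprocess.union_masks(masks, config.dilation_rounds)
    union = _union

    @stage("graph")
    def _graph():
        vg = graphify.extract_graph(union, config.min_hair_length_um,
                                    config.smoothing_sigma_vertices)
        return vg
    vgraph = _graph
    manifest["stages"]["graph"].update(
        segments=vgraph.n_segments, junctions=vgraph.n_junctions,
        endpoints=vgraph.n_endpoints)

    @stage("radii")
    def _radii():
        psf = PSFModel.gaussian((config.target_spacing,) * 3)
        decon = [radii.deconvolve(v, psf, config.rl_iterations) for v in vasc]
        priors = radii.prior_radius_dt(union, vgraph)
        table = radii.estimate_vertex_radii(decon, vgraph, priors,
                                            spacing=config.target_spacing)
        return radii.neuron_distance(neuron_mask, table)
    table = _radii

    @stage("metrics")
    def _metrics():
        summaries = netmetrics.summarize_vessels(
            table, vgraph, config.baseline_frames, config.post_frames,
            config.capillary_max_radius_um)
        summaries = netmetrics.classify_responders(summaries)
        fov_mm3 = float(np.prod(vasc[0].extent) * 1e-9)
        report = netmetrics.compute_morphometrics(
            vgraph, summaries, table, fov_mm3, neuron_mask,
            baseline_frames=config.baseline_frames)
        caps = summaries[summaries["size_class"] == "capillary"]
        values = dict(zip(caps["edge"], caps["delta_radius"]))
        lg = netmetrics.vessel_line_graph(vgraph, values)
        try:
            report["assortativity"] = netmetrics.assortativity(lg)
        except ValueError as exc:
            report["assortativity"] = None
            report["assortativity_note"] = str(exc)
        def tp_radii(frames):
            cols = [f"radius_t{t}" for t in frames]
            return dict(zip(summaries["edge"],
                            summaries[cols].mean(axis=1)))
        try:
            e_base = netmetrics.capillary_efficiency(
                vgraph, tp_radii(config.baseline_frames),
                config.efficiency_max_diameter_um, config.viscosity_cp)
            e_post = netmetrics.capillary_efficiency(
                vgraph, tp_radii(config.post_frames),
                config.efficiency_max_diameter_um, config.viscosity_cp,
                nodes=e_base.nodes)
            change = netmetrics.efficiency_change(e_base, e_post)
            report["efficiency_baseline"] = e_base.value
            report["efficiency_post"] = e_post.value
            report["efficiency_delta"] = change["delta"]
            report["efficiency_pct_change"] = change["pct_change"]
        except ValueError as exc:
            report["efficiency_note"] = str(exc)
        return summaries, report
    summaries, report = _metrics

    io.save_graphml(vgraph, out_dir / "graph.graphml")
    io.save_vertex_table(table, out_dir / "vertex_table.csv")
    summaries.to_csv(out_dir / "vessel_summaries.csv", index=False)
    io.save_report(report, out_dir / "network_report.json")
    io.save_report(manifest, out_dir / "manifest.json")
    return {"graph": vgraph, "vertex_table": table,
            "summaries": summaries, "report": report,
            "union_mask": union, "transforms": transforms,
            "manifest": manifest}
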