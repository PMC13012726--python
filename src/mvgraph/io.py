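"""Reading and writing the pipeline's file formats.

Volumes travel as multi-page TIFF (voxel size in ImageJ-style metadata) or
NIfTI; graphs as GraphML with vertex paths JSON-encoded on edges; vertex
tables and vessel summaries as CSV; transforms as 4×4 homogeneous matrices
in plain-text sidecars; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .graphify import VascularGraph
from .preprocess import RigidTransform
from .volume import BinaryMask, ImageVolume


def save_tiff(volume, path) -> None:
    """Write a volume (or mask) as a multi-page TIFF with voxel size."""
    path = Path(path)
    vs = volume.voxel_size  # (z, y, x) μm
    data = volume.voxels.astype(np.float32) if isinstance(volume, ImageVolume) \
        else volume.voxels.astype(np.uint8)
    tifffile.imwrite(
        path, data, imagej=True,
        resolution=(1.0 / vs[2], 1.0 / vs[1]),
        metadata={"spacing": vs[0], "unit": "um", "axes": "ZYX"},
    )


def load_tiff(path, voxel_size=None, channel: str = "vascular",
              as_mask: bool = False):
    """Read a multi-page TIFF; voxel size from metadata unless overridden."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if voxel_size is None:
            try:
                meta = tf.imagej_metadata or {}
                dz = float(meta.get("spacing", 1.0))
                tags = tf.pages[0].tags
                xres = tags["XResolution"].value
                yres = tags["YResolution"].value
                dx = xres[1] / xres[0]
                dy = yres[1] / yres[0]
                voxel_size = (dz, dy, dx)
            except (KeyError, TypeError, ZeroDivisionError):
                raise ValueError(
                    f"{path} lacks voxel-size metadata; pass voxel_size")
    if as_mask:
        return BinaryMask(data > 0, voxel_size)
    return ImageVolume(np.asarray(data, dtype=float), voxel_size, channel=channel)


def save_nifti(volume, path) -> None:
    """Write a volume as NIfTI (axes flipped to x, y, z on disk)."""
    vs = volume.voxel_size
    data = np.asarray(volume.voxels, dtype=np.float32).transpose(2, 1, 0)
    affine = np.diag([vs[2], vs[1], vs[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path, channel: str = "vascular", as_mask: bool = False):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if as_mask:
        return BinaryMask(data > 0, voxel_size)
    return ImageVolume(data.astype(float), voxel_size, channel=channel)


def load_volume(path, **kw):
    """Dispatch on suffix: .tif/.tiff or .nii/.nii.gz."""
    s = str(path)
    if s.endswith((".nii", ".nii.gz")):
        return load_nifti(path, **kw)
    return load_tiff(path, **kw)


def save_transform(transform: RigidTransform, path) -> None:
    np.savetxt(path, transform.as_matrix(),
               header="rigid transform, 4x4 homogeneous, (z,y,x) um")


def load_transform(path) -> RigidTransform:
    return RigidTransform.from_matrix(np.loadtxt(path))


def save_graphml(vgraph: VascularGraph, path) -> None:
    """GraphML export: node positions flat, edge paths JSON-encoded."""
    g = nx.MultiGraph()
    for n, d in vgraph.graph.nodes(data=True):
        p = d["position"]
        g.add_node(n, z=float(p[0]), y=float(p[1]), x=float(p[2]),
                   degree=int(d.get("degree", 0)))
    for u, v, k, d in vgraph.edges():
        attrs = {"length": float(d["length"]),
                 "path": json.dumps(np.asarray(d["path"]).tolist())}
        for extra in ("path_smooth", "tangent"):
            if extra in d:
                attrs[extra] = json.dumps(np.asarray(d[extra]).tolist())
        if "prior" in d:
            attrs["prior"] = float(d["prior"])
        g.add_edge(u, v, key=k, **attrs)
    nx.write_graphml(g, str(path))


def load_graphml(path, voxel_size=(0.99, 0.99, 0.99)) -> VascularGraph:
    g0 = nx.read_graphml(str(path), force_multigraph=True)
    g = nx.MultiGraph()
    relabel = {n: i for i, n in enumerate(g0.nodes)}
    for n, d in g0.nodes(data=True):
        g.add_node(relabel[n],
                   position=np.array([d["z"], d["y"], d["x"]], dtype=float),
                   degree=int(d.get("degree", 0)))
    for u, v, k, d in g0.edges(keys=True, data=True):
        attrs = {"length": float(d["length"]),
                 "path": np.array(json.loads(d["path"]))}
        for extra in ("path_smooth", "tangent"):
            if extra in d:
                attrs[extra] = np.array(json.loads(d[extra]))
        g.add_edge(relabel[u], relabel[v], **attrs)
    return VascularGraph(g, tuple(voxel_size))


def save_vertex_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_vertex_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default))


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
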