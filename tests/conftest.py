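"""Shared phantom fixtures for the test suite.

All fixtures are generated programmatically and deterministically; nothing
is loaded from disk.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from mvgraph import (PhantomSpec, PSFModel, SphereSpec, TubeSpec,
                     apply_psf_and_noise, generate_phantom)
from mvgraph.graphify import VascularGraph


@pytest.fixture(scope="session")
def psf():
    return PSFModel.gaussian()


@pytest.fixture(scope="session")
def straight_tube():
    """Straight tube along z, radius 3 μm, two time points (×1.0, ×1.10)."""
    ext = 60 * 0.99
    spec = PhantomSpec(
        (61, 41, 41),
        tubes=[TubeSpec([[2.0, 20 * 0.99, 20 * 0.99],
                         [ext - 2.0, 20 * 0.99, 20 * 0.99]], 3.0)],
        timepoints=[1.0, 1.10],
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def y_phantom():
    """Three tubes meeting at one junction, plus two neuron somas."""
    c = np.array([24.5, 39.5, 39.5])
    tips = [c + np.array([20, 28, 5]),
            c + np.array([-18, -30, 12]),
            c + np.array([5, 8, -34])]
    spec = PhantomSpec(
        (51, 81, 81),
        tubes=[TubeSpec(np.vstack([c, t]), r)
               for t, r in zip(tips, [3.0, 2.5, 2.0])],
        neurons=[SphereSpec(c + np.array([10, 25, 25]), 5.0, 500.0),
                 SphereSpec(c + np.array([-12, -20, 18]), 6.0, 500.0)],
        timepoints=[1.0, [1.02] * 3, [0.98] * 3, [1.10, 1.0, 1.0]],
        seed=0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def rich_phantom_builder(psf):
    """Factory for registration phantoms: asymmetric multi-tube content.

    ``build(offset, rot_deg, seed)`` applies the rotation about the volume
    center and the translation to every primitive, then adds noise.
    """
    def build(offset=np.zeros(3), rot_deg=0.0, seed=1, noise=10.0):
        c = np.array([19.3] * 3)
        tips = [c + np.array([14, 10, 3]), c + np.array([-12, -9, 6]),
                c + np.array([3, 6, -14]), c + np.array([-4, 8, 13]),
                c + np.array([12, -11, -7])]
        cps = [np.vstack([c, t]) for t in tips]
        beads = [c + np.array([-10, 11, -8]), c + np.array([9, -12, 10])]
        if rot_deg:
            th = np.deg2rad(rot_deg)
            rot = np.array([[1, 0, 0],
                            [0, np.cos(th), -np.sin(th)],
                            [0, np.sin(th), np.cos(th)]])
            cps = [(cp - c) @ rot.T + c for cp in cps]
            beads = [rot @ (b - c) + c for b in beads]
        spec = PhantomSpec(
            (40, 40, 40),
            tubes=[TubeSpec(cp + offset, r)
                   for cp, r in zip(cps, [3.0, 2.5, 2.0, 1.8, 2.2])],
            beads=[SphereSpec(b + offset, r, 600.0)
                   for b, r in zip(beads, [2.5, 3.0])],
        )
        data = generate_phantom(spec)
        return apply_psf_and_noise(data.volumes[0]["vascular"], psf,
                                   noise_sigma=noise, seed=seed)
    return build


def make_metric_graph(edges, voxel_size=(0.99, 0.99, 0.99)) -> VascularGraph:
    """VascularGraph from (u, v, length_um) triples, for metric tests.

    Edge paths are straight two-vertex stubs; node positions arbitrary.
    """
    g = nx.MultiGraph()
    nodes = {n for u, v, _ in edges for n in (u, v)}
    for n in nodes:
        g.add_node(n, position=np.array([0.0, 0.0, float(n)]))
    for u, v, length in edges:
        path = np.array([[0.0, 0.0, float(u)], [0.0, 0.0, float(u) + length]])
        g.add_edge(u, v, path=path, length=float(length))
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree(n)
    return VascularGraph(g, voxel_size)
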