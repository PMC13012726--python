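"""Vessel- and network-level analysis of reconstructed vascular graphs.

Vessel summaries aggregate vertex-wise radii into per-segment baselines and
stimulation-induced changes; responders are vessels whose mean radius moves
by more than twice their baseline standard deviation.  Network coordination
is quantified by the assortativity of radius changes on the vessel
adjacency (line) graph — the Pearson correlation of changes on connected
vessels — and by the hydraulic efficiency of the capillary bed, built from
Poiseuille resistances ρ = 8μL/(πR⁴) and least-resistive paths between
junctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .graphify import VascularGraph
from .volume import BinaryMask

CP_TO_PA_S = 1e-3
UM_TO_M = 1e-6
CAPILLARY_MAX_RADIUS_UM = 5.0     # capillary vs large-vessel split
RESPONDER_MIN_LENGTH_UM = 20.0    # vessels at/below this are never responders
EFFICIENCY_MAX_DIAMETER_UM = 10.0
DEFAULT_VISCOSITY_CP = 4.0


def summarize_vessels(
    vertex_table: pd.DataFrame,
    vgraph: VascularGraph,
    baseline_frames: list[int],
    post_frames: list[int],
    capillary_max_radius: float = CAPILLARY_MAX_RADIUS_UM,
) -> pd.DataFrame:
    """Per-vessel summary: baseline radius, variability, and change.

    The baseline standard deviation is the SD of the edge's mean radius
    across baseline time points; ``delta_radius`` is the post-stimulus mean
    minus the baseline mean of the same quantity.
    """
    lengths = {eid: d["length"]
               for eid, (_, _, _, d) in enumerate(vgraph.edges())}
    term = set()
    for eid, (u, v, _, _) in enumerate(vgraph.edges()):
        if vgraph.graph.nodes[u]["degree"] == 1 or vgraph.graph.nodes[v]["degree"] == 1:
            term.add(eid)
    rows = []
    for eid, grp in vertex_table.groupby("edge"):
        tp_means = {}
        for col in grp.columns:
            if col.startswith("radius_t"):
                tp_means[int(col[len("radius_t"):])] = grp[col].mean()
        base = np.array([tp_means[t] for t in baseline_frames])
        post = np.array([tp_means[t] for t in post_frames])
        base_mean = float(np.nanmean(base))
        base_sd = float(np.nanstd(base, ddof=1)) if np.isfinite(base).sum() > 1 else np.nan
        delta = float(np.nanmean(post)) - base_mean
        row = {
            "edge": eid,
            "length": lengths.get(eid, np.nan),
            "baseline_radius_mean": base_mean,
            "baseline_radius_sd": base_sd,
            "delta_radius": delta,
            "mean_depth": float(grp["z"].mean()),
            "terminal": eid in term,
            "size_class": "capillary" if base_mean < capillary_max_radius else "large",
        }
        for t, m in tp_means.items():
            row[f"radius_t{t}"] = m
        if "neuron_distance" in grp.columns:
            row["min_neuron_distance"] = float(grp["neuron_distance"].min())
        rows.append(row)
    return pd.DataFrame(rows)


def classify_responders(
    summaries: pd.DataFrame,
    min_length: float = RESPONDER_MIN_LENGTH_UM,
    sd_gate: float = 2.0,
) -> pd.DataFrame:
    """Label each vessel dilator / constrictor / none.

    A vessel is a responder iff |delta_radius| exceeds ``sd_gate`` × its
    baseline SD *and* it is longer than ``min_length`` μm (short vessels
    average too few cross-sections to be trusted).  Vessels with a single
    baseline time point have undefined baseline SD and are excluded with a
    warning.
    """
    out = summaries.copy()
    undefined = ~np.isfinite(out["baseline_radius_sd"])
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} vessel(s) lack >=2 baseline "
                      "time points; excluded from responder classification")
    gate = sd_gate * out["baseline_radius_sd"]
    resp = np.where(
        undefined | (out["length"] <= min_length), "none",
        np.where(out["delta_radius"] > gate, "dilator",
                 np.where(out["delta_radius"] < -gate, "constrictor", "none")),
    )
    out["responder"] = resp
    out.loc[undefined, "responder"] = "excluded"
    return out


def vessel_line_graph(
    vgraph: VascularGraph,
    values: dict[int, float],
    include: set[int] | None = None,
) -> nx.Graph:
    """Vessel adjacency graph: vessels are nodes, shared junctions links.

    ``values`` attaches a scalar (e.g. delta_radius) to each included
    vessel; vessels sharing at least one junction node are linked.
    """
    edges = list(vgraph.edges())
    if include is None:
        include = set(values.keys())
    lg = nx.Graph()
    incident: dict[int, list[int]] = {}
    for eid, (u, v, k, _) in enumerate(edges):
        if eid not in include:
            continue
        lg.add_node(eid, value=float(values[eid]))
        for node in {u, v}:
            incident.setdefault(node, []).append(eid)
    for node, eids in incident.items():
        for i in range(len(eids)):
            for j in range(i + 1, len(eids)):
                if eids[i] != eids[j]:
                    lg.add_edge(eids[i], eids[j])
    return lg


def assortativity(line_graph: nx.Graph, attribute: str = "value") -> float:
    """Pearson correlation of the attribute across linked vessel pairs.

    Every undirected link contributes both orientations, making the
    statistic symmetric (the standard numeric assortativity).  Raises on
    fewer than two links or zero variance of the endpoint values — an
    undefined correlation is never silently reported as 0.
    """
    if line_graph.number_of_edges() < 2:
        raise ValueError("assortativity needs at least 2 links")
    xs, ys = [], []
    for a, b in line_graph.edges():
        va = line_graph.nodes[a][attribute]
        vb = line_graph.nodes[b][attribute]
        xs.extend([va, vb])
        ys.extend([vb, va])
    xs, ys = np.array(xs), np.array(ys)
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance of endpoint values: q undefined")
    return float(np.corrcoef(xs, ys)[0, 1])


def edge_resistance(length_um: float, radius_um: float,
                    viscosity_cp: float = DEFAULT_VISCOSITY_CP) -> float:
    """Poiseuille resistance ρ = 8μL/(πR⁴) in Pa·s·m⁻³."""
    if radius_um <= 0 or length_um <= 0:
        raise ValueError("length and radius must be positive")
    mu = viscosity_cp * CP_TO_PA_S
    return 8.0 * mu * (length_um * UM_TO_M) / (np.pi * (radius_um * UM_TO_M) ** 4)


@dataclass
class EfficiencyResult:
    """Capillary network efficiency and the node set it was computed on."""

    value: float                 # Pa⁻¹·s⁻¹·m³ (inverse resistance), averaged
    n_nodes: int
    nodes: frozenset

    @property
    def value_per_peta_ohm(self) -> float:
        """Efficiency in PΩ⁻¹ (1 PΩ ≡ 1e15 Pa·s·m⁻³)."""
        return self.value * 1e15


def capillary_efficiency(
    vgraph: VascularGraph,
    edge_radii: dict[int, float],
    max_diameter_um: float = EFFICIENCY_MAX_DIAMETER_UM,
    viscosity_cp: float = DEFAULT_VISCOSITY_CP,
    nodes: frozenset | None = None,
) -> EfficiencyResult:
    """Average inverse least-resistive-path resistance between junctions.

    Vessels wider than ``max_diameter_um`` are excluded so the statistic
    reflects the capillary nexus; the node set is the junctions of the
    retained subgraph (or a caller-fixed ``nodes`` set, for comparing time
    points on identical nodes).  Disconnected pairs contribute zero inverse
    resistance (no flow path).
    """
    g = nx.MultiGraph()
    for eid, (u, v, k, data) in enumerate(vgraph.edges()):
        r = edge_radii.get(eid, np.nan)
        if not np.isfinite(r) or 2.0 * r > max_diameter_um:
            continue
        rho = edge_resistance(data["length"], r, viscosity_cp)
        g.add_edge(u, v, resistance=rho)
    node_set = frozenset(g.nodes) if nodes is None else nodes
    n = len(node_set)
    if n < 2:
        raise ValueError("capillary subgraph has fewer than 2 junctions")
    total = 0.0
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="resistance"))
    for i in node_set:
        row = lengths.get(i, {})
        for j in node_set:
            if i == j:
                continue
            rho_ij = row.get(j, np.inf)
            if rho_ij > 0 and np.isfinite(rho_ij):
                total += 1.0 / rho_ij
    return EfficiencyResult(total / (n * (n - 1)), n, node_set)


def efficiency_change(baseline: EfficiencyResult,
                      post: EfficiencyResult) -> dict:
    """Stimulation-induced change in efficiency from its baseline level."""
    if baseline.nodes != post.nodes:
        raise ValueError("efficiencies computed on different node sets")
    delta = post.value - baseline.value
    return {"delta": delta,
            "pct_change": 100.0 * delta / baseline.value}


def compute_morphometrics(
    vgraph: VascularGraph,
    summaries: pd.DataFrame,
    vertex_table: pd.DataFrame,
    fov_volume_mm3: float,
    neuron_mask: BinaryMask | None = None,
    baseline_frames: list[int] | None = None,
) -> dict:
    """Network morphometrics: counts, densities, lengths, volumes.

    Densities are counts per field-of-view volume; cumulative length
    density is reported in m/mm³ and vascular volume density in mm³/mm³
    (Σ π r² × vertex spacing along every edge, using baseline radii).
    """
    if fov_volume_mm3 <= 0:
        raise ValueError("FOV volume must be positive")
    g = vgraph.graph
    n_junctions = sum(1 for _, d in g.nodes(data=True) if d["degree"] >= 3)
    n_vessels = g.number_of_edges()
    n_terminal = int(summaries["terminal"].sum()) if "terminal" in summaries \
        else sum(1 for _, d in g.nodes(data=True) if d["degree"] == 1)
    lengths = summaries["length"].to_numpy()
    base_cols = [f"radius_t{t}" for t in (baseline_frames or [0])]
    # vascular volume: integrate pi r^2 along each edge's vertex path
    volume_um3 = 0.0
    for eid, grp in vertex_table.groupby("edge"):
        pos = grp[["z", "y", "x"]].to_numpy()
        if pos.shape[0] < 2:
            continue
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        r = np.nanmean(grp[[c for c in base_cols if c in grp.columns]].to_numpy(),
                       axis=1)
        r_mid = 0.5 * (r[:-1] + r[1:])
        ok = np.isfinite(r_mid)
        volume_um3 += float(np.sum(np.pi * r_mid[ok] ** 2 * seg[ok]))
    report = {
        "vessel_count": n_vessels,
        "vessel_density_mm3": n_vessels / fov_volume_mm3,
        "junction_count": n_junctions,
        "junction_density_mm3": n_junctions / fov_volume_mm3,
        "terminal_vessel_count": n_terminal,
        "mean_segment_length_um": float(np.nanmean(lengths)),
        "cumulative_length_density_m_per_mm3":
            float(np.nansum(lengths)) * UM_TO_M / fov_volume_mm3,
        "mean_baseline_radius_um": float(summaries["baseline_radius_mean"].mean()),
        "mean_intravessel_radius_sd_um": float(
            vertex_table.groupby("edge")[base_cols[0]].std().mean())
            if base_cols[0] in vertex_table else np.nan,
        "vascular_volume_density": volume_um3 * 1e-9 / fov_volume_mm3,
    }
    if neuron_mask is not None:
        labels, n_neurons = ndimage.label(
            neuron_mask.voxels, structure=np.ones((3, 3, 3), dtype=bool))
        report["neuron_count"] = int(n_neurons)
        report["neuron_density_mm3"] = n_neurons / fov_volume_mm3
    return report
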