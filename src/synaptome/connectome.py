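"""Connectome derivation and morphometric analyses.

The connectome is the directed multigraph over neuron identifiers with one
edge per synapse.  The topologic model level suffices to build it; the
point level additionally enables spatial synaptic-density maps, and the
geometric level terminal-size distributions.

Operational definitions (the source model names but does not define
these): a *microcircuit* is a simple directed path of synapses, a *loop*
a simple directed cycle, and a *feedback* a reciprocally connected neuron
pair.  Counts are at the neuron level — parallel synapses between the
same neuron pair collapse to one edge for path/cycle purposes, with their
multiplicity reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .codec import DecodedSynaptome
from .core import ModelLevel, ModelVariant, Synaptome
from .errors import CapabilityError, SizeError, ValidationError

__all__ = [
    "build_graph",
    "to_simple_graph",
    "count_loops",
    "count_feedbacks",
    "microcircuits",
    "path_multiplicity",
    "density_grid",
    "radius_distribution",
    "graph_to_edgelist",
    "DEFAULT_NODE_BOUND",
]

# Exhaustive cycle enumeration is exponential; refuse beyond this many
# nodes unless the caller raises the bound explicitly.
DEFAULT_NODE_BOUND = 20


def build_graph(synaptome: Synaptome | DecodedSynaptome) -> nx.MultiDiGraph:
    """Directed multigraph over neuron ids, one edge per synapse.

    Accepts an in-memory synaptome or any decoded record set that carries
    neuron identifiers (the neuron-terminal scheme at any level).  Edges
    are annotated with the synapse index and, when the level provides
    them, the synapse location (terminal-centre midpoint) and radii.
    """
    g = nx.MultiDiGraph()
    if isinstance(synaptome, Synaptome):
        for idx, s in enumerate(synaptome):
            g.add_edge(
                s.pre.neuron_id,
                s.post.neuron_id,
                key=idx,
                synapse_index=idx,
                location=s.midpoint,
                pre_radius=s.pre.radius,
                post_radius=s.post.radius,
            )
        return g

    rec = synaptome.records
    if "pre_neuron" not in rec.columns:
        raise CapabilityError(
            "synapse-id records carry no neuron identifiers; "
            "a connectome graph needs the neuron-terminal scheme"
        )
    for idx, row in enumerate(rec.itertuples(index=False)):
        attrs: dict = {"synapse_index": idx}
        if synaptome.has_locations:
            if "x" in rec.columns:  # simplified: merged location
                attrs["location"] = (row.x, row.y, row.z)
            else:
                attrs["location"] = (
                    (row.pre_x + row.post_x) / 2,
                    (row.pre_y + row.post_y) / 2,
                    (row.pre_z + row.post_z) / 2,
                )
        if synaptome.has_radii:
            if "r" in rec.columns:
                attrs["mean_radius"] = row.r
            else:
                attrs["pre_radius"] = row.pre_r
                attrs["post_radius"] = row.post_r
        g.add_edge(int(row.pre_neuron), int(row.post_neuron), key=idx, **attrs)
    return g


def to_simple_graph(g: nx.MultiDiGraph) -> nx.DiGraph:
    """Collapse parallel synapses to one edge, keeping the multiplicity."""
    sg = nx.DiGraph()
    sg.add_nodes_from(g.nodes)
    for u, v in g.edges():
        if sg.has_edge(u, v):
            sg[u][v]["multiplicity"] += 1
        else:
            sg.add_edge(u, v, multiplicity=1)
    return sg


def _check_size(g, node_bound: int) -> None:
    if g.number_of_nodes() > node_bound:
        raise SizeError(
            f"graph has {g.number_of_nodes()} nodes; exhaustive enumeration "
            f"is limited to {node_bound} (raise node_bound to override)"
        )


def count_loops(
    g: nx.MultiDiGraph | nx.DiGraph,
    max_length: int,
    node_bound: int = DEFAULT_NODE_BOUND,
) -> int:
    """Number of simple directed cycles of length <= ``max_length``.

    Cycles are counted on the neuron-level simple graph (parallel
    synapses collapsed); self-loops from autapses count as length-1
    cycles.  Exact exhaustive enumeration, gated by ``node_bound``.
    """
    if max_length < 2:
        raise ValidationError(f"max_length must be >= 2, got {max_length}")
    _check_size(g, node_bound)
    sg = to_simple_graph(g) if g.is_multigraph() else g
    return sum(1 for _ in nx.simple_cycles(sg, length_bound=max_length))


def count_feedbacks(g: nx.MultiDiGraph | nx.DiGraph) -> int:
    """Number of unordered neuron pairs {i, j} connected both ways."""
    sg = to_simple_graph(g) if g.is_multigraph() else g
    return sum(
        1 for u, v in sg.edges() if u < v and sg.has_edge(v, u)
    )


def microcircuits(
    g: nx.MultiDiGraph | nx.DiGraph,
    source,
    target,
    max_length: int,
    node_bound: int = DEFAULT_NODE_BOUND,
) -> list[list]:
    """All simple directed paths from source to target with at most
    ``max_length`` synaptic steps, as node sequences."""
    if source not in g or target not in g:
        missing = [x for x in (source, target) if x not in g]
        raise ValidationError(f"node(s) not in graph: {missing}")
    _check_size(g, node_bound)
    sg = to_simple_graph(g) if g.is_multigraph() else g
    return [list(p) for p in nx.all_simple_paths(sg, source, target,
                                                 cutoff=max_length)]


def path_multiplicity(g: nx.MultiDiGraph, path: list) -> int:
    """Number of distinct synapse sequences realizing a neuron-level path
    (the product of parallel-synapse counts along its edges)."""
    mult = 1
    for u, v in zip(path[:-1], path[1:]):
        mult *= g.number_of_edges(u, v)
    return mult


def _midpoints(synaptome: Synaptome | DecodedSynaptome) -> np.ndarray:
    if isinstance(synaptome, Synaptome):
        return np.array([s.midpoint for s in synaptome], dtype=float)
    rec = synaptome.records
    if not synaptome.has_locations:
        raise CapabilityError(
            "topologic records carry no locations; synaptic densities "
            "need at least the point model"
        )
    if "x" in rec.columns:
        return rec[["x", "y", "z"]].to_numpy(dtype=float)
    pre = rec[["pre_x", "pre_y", "pre_z"]].to_numpy(dtype=float)
    post = rec[["post_x", "post_y", "post_z"]].to_numpy(dtype=float)
    return (pre + post) / 2


def density_grid(
    synaptome: Synaptome | DecodedSynaptome,
    bin_nm: float,
    extent_nm: float | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Histogram of synapse midpoint locations over cubic spatial bins.

    Returns the 3-D count array and the bin edges per axis.  The total
    count equals the synapse count exactly.
    """
    if bin_nm <= 0:
        raise ValidationError(f"bin_nm must be > 0, got {bin_nm}")
    if extent_nm is None:
        profile = getattr(synaptome, "profile", None)
        if profile is None:
            raise ValidationError("extent_nm required when no profile is set")
        extent_nm = profile.extent_nm
    mid = _midpoints(synaptome)
    n_bins = max(1, int(np.ceil(extent_nm / bin_nm)))
    if mid.size == 0:
        mid = np.empty((0, 3))
    counts, edges = np.histogramdd(
        mid, bins=(n_bins, n_bins, n_bins),
        range=[(0.0, n_bins * bin_nm)] * 3,
    )
    return counts, edges


def radius_distribution(
    synaptome: Synaptome | DecodedSynaptome,
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of terminal radii (geometric level only).

    A full synaptome contributes both terminal radii per synapse
    (2 x n_synapses values); a simplified record set contributes one mean
    radius per synapse.
    """
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    if isinstance(synaptome, Synaptome):
        radii = np.array(
            [r for s in synaptome for r in (s.pre.radius, s.post.radius)],
            dtype=float,
        )
    else:
        if not synaptome.has_radii:
            raise CapabilityError(
                "terminal-size distributions need the geometric model"
            )
        rec = synaptome.records
        if "r" in rec.columns:
            radii = rec["r"].to_numpy(dtype=float)
        else:
            radii = np.concatenate(
                [rec["pre_r"].to_numpy(dtype=float),
                 rec["post_r"].to_numpy(dtype=float)]
            )
    if radii.size == 0:
        return np.zeros(n_bins, dtype=int), np.linspace(0.0, 1.0, n_bins + 1)
    return np.histogram(radii, bins=n_bins,
                        range=(radii.min(), radii.max()))


def graph_to_edgelist(g: nx.MultiDiGraph) -> pd.DataFrame:
    """Edge list with columns pre_neuron, post_neuron, synapse_index."""
    rows = [
        (u, v, data.get("synapse_index", key))
        for u, v, key, data in g.edges(keys=True, data=True)
    ]
    rows.sort(key=lambda r: r[2])
    return pd.DataFrame(rows,
                        columns=["pre_neuron", "post_neuron", "synapse_index"])
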