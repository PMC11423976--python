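"""Independent brute-force graph oracles.

Deliberately naive depth-first enumerations, kept free of networkx so the
connectome module's counts can be checked against a second route.
"""

from __future__ import annotations

import random


def random_digraph(seed: int, max_nodes: int = 10) -> tuple[list[int], set]:
    """Seeded random directed graph (node list, edge set), <= max_nodes."""
    rng = random.Random(seed)
    n = rng.randint(2, max_nodes)
    nodes = list(range(n))
    p = rng.uniform(0.1, 0.5)
    edges = {
        (u, v)
        for u in nodes
        for v in nodes
        if rng.random() < p
    }
    return nodes, edges


def _adjacency(nodes, edges):
    adj = {v: [] for v in nodes}
    for u, v in edges:
        adj[u].append(v)
    return adj


def brute_force_cycles(nodes, edges, max_length: int) -> int:
    """Count simple directed cycles of length <= max_length.

    Each cycle is counted once by requiring its smallest node to be the
    start of the walk; self-loops are length-1 cycles.
    """
    adj = _adjacency(nodes, edges)
    count = 0

    def walk(start, current, visited, length):
        nonlocal count
        for nxt in adj[current]:
            if nxt == start:
                if length <= max_length:
                    count += 1
            elif nxt > start and nxt not in visited and length < max_length:
                visited.add(nxt)
                walk(start, nxt, visited, length + 1)
                visited.remove(nxt)

    for start in nodes:
        walk(start, start, {start}, 1)
    return count


def brute_force_feedbacks(edges) -> int:
    """Unordered pairs {u, v}, u != v, with both directed edges present."""
    return sum(1 for (u, v) in edges if u < v and (v, u) in edges)


def brute_force_paths(nodes, edges, source, target, max_length) -> list[list]:
    """All simple directed paths source -> target of <= max_length steps."""
    adj = _adjacency(nodes, edges)
    out: list[list] = []

    def walk(current, path):
        if current == target and len(path) > 1:
            out.append(list(path))
            return
        if len(path) - 1 >= max_length:
            return
        for nxt in adj[current]:
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    if source == target:
        return []
    walk(source, [source])
    return out
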