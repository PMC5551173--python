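"""Shared family of small areal graphs used by ICAR consistency checks."""

import numpy as np

from carmap.graphs import AreaGraph, build_lattice_graph


def _random_connected_graph(n: int, p: float, seed: int) -> AreaGraph:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    edges = {tuple(sorted((order[k], order[k + 1]))) for k in range(n - 1)}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((i, j))
    nb = [[] for _ in range(n)]
    for i, j in edges:
        nb[i].append(j)
        nb[j].append(i)
    return AreaGraph(nb)


def small_graph_family() -> list[AreaGraph]:
    """Connected graphs with 2..10 areas: paths, cycles, stars, complete
    graphs, a lattice, and seeded random graphs."""
    graphs: list[AreaGraph] = []
    # paths
    for n in (2, 3, 5, 10):
        graphs.append(
            AreaGraph([[j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)])
        )
    # cycles
    for n in (4, 7):
        graphs.append(AreaGraph([[(i - 1) % n, (i + 1) % n] for i in range(n)]))
    # stars
    for n in (4, 8):
        graphs.append(AreaGraph([list(range(1, n))] + [[0] for _ in range(n - 1)]))
    # complete graphs
    for n in (3, 5):
        graphs.append(
            AreaGraph([[j for j in range(n) if j != i] for i in range(n)])
        )
    graphs.append(build_lattice_graph(3, 3))
    graphs.append(build_lattice_graph(2, 5))
    for seed in range(6):
        n = 4 + (seed * 7) % 7  # sizes 4..10
        graphs.append(_random_connected_graph(n, 0.35, seed))
    assert all(g.n_areas <= 10 for g in graphs)
    return graphs
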