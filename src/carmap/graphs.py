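"""Areal adjacency graphs and intrinsic-CAR (ICAR) primitives.

The spatially structured random effect of a BYM-type disease-mapping model
follows an intrinsic conditional autoregressive prior: each area's effect is
Gaussian around the mean of its neighbours' effects with variance
``sigma_phi**2 / n_i``, where ``n_i`` is the number of neighbours.  The joint
(improper) density implied by those conditionals is the pairwise-difference
form

    log p(phi) = -(1 / (2 sigma_phi^2)) * sum_{i<j, i~j} (phi_i - phi_j)^2 + const,

improper along the constant vector; identifiability is restored by a
sum-to-zero constraint on ``phi``.

This module provides the graph container (:class:`AreaGraph`), lattice
construction, GAL neighbour-list I/O, and the ICAR conditional / joint /
sampling primitives used by both the simulator and the MCMC engine.
"""

from __future__ import annotations

from typing import Sequence, TextIO

import numpy as np


class GraphStructureError(ValueError):
    """Raised for graphs that violate the model's structural requirements."""


class GalFormatError(ValueError):
    """Raised for malformed GAL neighbour-list input."""


class AreaGraph:
    """Symmetric, connected areal adjacency without self-loops.

    Parameters
    ----------
    neighbors
        Per-area sequences of 0-based neighbour indices.

    Notes
    -----
    Validation enforces symmetry, absence of self-loops, ``n_i >= 1`` for
    every area and connectedness.  Disconnected graphs (or islands) are
    rejected rather than patched: silently accommodating islands changes the
    ICAR model.
    """

    def __init__(self, neighbors: Sequence[Sequence[int]]):
        self.neighbors: tuple[tuple[int, ...], ...] = tuple(
            tuple(sorted(int(j) for j in nb)) for nb in neighbors
        )
        self.n_areas: int = len(self.neighbors)
        if self.n_areas < 2:
            raise GraphStructureError("an areal graph needs at least 2 areas")
        self._validate()
        self.n_i: np.ndarray = np.array([len(nb) for nb in self.neighbors])
        # edge list with i < j, each undirected edge once
        self.edges: np.ndarray = np.array(
            [(i, j) for i, nb in enumerate(self.neighbors) for j in nb if i < j],
            dtype=np.int64,
        ).reshape(-1, 2)
        self._eigen: tuple[np.ndarray, np.ndarray] | None = None
        self._coloring: np.ndarray | None = None

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        n = self.n_areas
        seen = [set(nb) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if len(nb) == 0:
                raise GraphStructureError(f"area {i} has no neighbors")
            if i in nb:
                raise GraphStructureError(f"area {i} lists itself as a neighbor")
            if len(set(nb)) != len(nb):
                raise GraphStructureError(f"area {i} lists a duplicate neighbor")
            for j in nb:
                if not 0 <= j < n:
                    raise GraphStructureError(
                        f"area {i} lists out-of-range neighbor {j}"
                    )
                if i not in seen[j]:
                    raise GraphStructureError(
                        f"asymmetric adjacency: {j} in neighbors({i}) "
                        f"but {i} not in neighbors({j})"
                    )
        # connectivity by BFS
        visited = np.zeros(n, dtype=bool)
        stack = [0]
        visited[0] = True
        while stack:
            i = stack.pop()
            for j in self.neighbors[i]:
                if not visited[j]:
                    visited[j] = True
                    stack.append(j)
        if not visited.all():
            raise GraphStructureError(
                f"graph is disconnected ({int(visited.sum())} of {n} areas reachable)"
            )

    # -- linear algebra helpers ----------------------------------------
    def adjacency_matrix(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix."""
        a = np.zeros((self.n_areas, self.n_areas))
        a[self.edges[:, 0], self.edges[:, 1]] = 1.0
        a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian D - A; the ICAR precision is L / sigma_phi^2."""
        return np.diag(self.n_i.astype(float)) - self.adjacency_matrix()

    def _eigenbasis(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenpairs of the Laplacian restricted to the non-null space.

        Cached; used for exact ICAR sampling under the sum-to-zero
        constraint.  For a connected graph the null space is spanned by the
        constant vector only.
        """
        if self._eigen is None:
            lam, vec = np.linalg.eigh(self.laplacian())
            keep = lam > 1e-9 * lam[-1]
            self._eigen = (lam[keep], vec[:, keep])
        return self._eigen

    def coloring(self) -> np.ndarray:
        """Greedy proper vertex colouring (per-area colour ids).

        Areas of equal colour are mutually non-adjacent, hence conditionally
        independent under the ICAR prior given the rest; the sampler uses
        this to update whole colour classes at once.
        """
        if self._coloring is None:
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(self.n_areas))
            g.add_edges_from(map(tuple, self.edges))
            col = nx.greedy_color(g, strategy="largest_first")
            self._coloring = np.array([col[i] for i in range(self.n_areas)])
        return self._coloring

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AreaGraph) and self.neighbors == other.neighbors

    def __repr__(self) -> str:
        return f"AreaGraph(n_areas={self.n_areas}, n_edges={len(self.edges)})"


def build_lattice_graph(rows: int, cols: int) -> AreaGraph:
    """Rook-adjacency rectangular lattice of ``rows x cols`` areas.

    A stand-in for real areal systems: interior cells have 4 neighbours,
    edge cells 3, corner cells 2.  Areas are numbered row-major.
    """
    if rows < 2 or cols < 2:
        raise ValueError("lattice dimensions must both be >= 2")
    neighbors: list[list[int]] = []
    for r in range(rows):
        for c in range(cols):
            nb = []
            if r > 0:
                nb.append((r - 1) * cols + c)
            if r < rows - 1:
                nb.append((r + 1) * cols + c)
            if c > 0:
                nb.append(r * cols + c - 1)
            if c < cols - 1:
                nb.append(r * cols + c + 1)
            neighbors.append(nb)
    return AreaGraph(neighbors)


# ---------------------------------------------------------------------------
# GAL neighbour-list I/O.  Dialect: a header line whose last token is the
# area count (a leading "0" as in classic GAL headers is tolerated), then per
# area a line "id n_neighbors" followed by one line of neighbour ids.
# On-disk ids are 1-based; in memory everything is 0-based.
# ---------------------------------------------------------------------------

def read_adjacency(text: str, strict: bool = True) -> AreaGraph:
    """Parse a GAL neighbour list into an :class:`AreaGraph`.

    With ``strict=True`` (default) asymmetric listings are rejected; with
    ``strict=False`` they are repaired by symmetrisation.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise GalFormatError("empty GAL input")
    header = lines[0].split()
    try:
        n = int(header[-1])
    except ValueError as exc:
        raise GalFormatError(f"malformed GAL header: {lines[0]!r}") from exc
    if n < 1:
        raise GalFormatError(f"GAL header declares non-positive area count {n}")
    neighbors: list[set[int]] = [set() for _ in range(n)]
    seen = np.zeros(n, dtype=bool)
    pos = 1
    for _ in range(n):
        if pos + 1 >= len(lines) + 1:
            raise GalFormatError("GAL input truncated before all areas were read")
        head = lines[pos].split()
        if len(head) != 2:
            raise GalFormatError(f"expected 'id count' on line {pos + 1}: {lines[pos]!r}")
        ident, count = (int(tok) for tok in head)
        if not 1 <= ident <= n:
            raise GalFormatError(f"area id {ident} on line {pos + 1} outside 1..{n}")
        if seen[ident - 1]:
            raise GalFormatError(f"area id {ident} listed twice (line {pos + 1})")
        seen[ident - 1] = True
        if count < 1:
            raise GalFormatError(f"area {ident} declares {count} neighbors (need >= 1)")
        if pos + 1 >= len(lines):
            raise GalFormatError(f"missing neighbor line for area {ident}")
        ids = [int(tok) for tok in lines[pos + 1].split()]
        if len(ids) != count:
            raise GalFormatError(
                f"area {ident}: declared {count} neighbors, found {len(ids)} "
                f"(line {pos + 2})"
            )
        for j in ids:
            if not 1 <= j <= n:
                raise GalFormatError(
                    f"area {ident} lists neighbor id {j} outside 1..{n} (line {pos + 2})"
                )
        neighbors[ident - 1] = {j - 1 for j in ids}
        pos += 2
    if strict:
        for i in range(n):
            for j in neighbors[i]:
                if i not in neighbors[j]:
                    raise GalFormatError(
                        f"asymmetric adjacency: area {i + 1} lists {j + 1} "
                        f"but not vice versa"
                    )
    else:
        for i in range(n):
            for j in list(neighbors[i]):
                neighbors[j].add(i)
    return AreaGraph([sorted(nb) for nb in neighbors])


def write_adjacency(graph: AreaGraph, fh: TextIO | None = None) -> str:
    """Serialise an :class:`AreaGraph` as GAL text (1-based ids on disk)."""
    out = [str(graph.n_areas)]
    for i, nb in enumerate(graph.neighbors):
        out.append(f"{i + 1} {len(nb)}")
        out.append(" ".join(str(j + 1) for j in nb))
    text = "\n".join(out) + "\n"
    if fh is not None:
        fh.write(text)
    return text


# ---------------------------------------------------------------------------
# ICAR primitives
# ---------------------------------------------------------------------------

def icar_conditional(
    phi: np.ndarray, graph: AreaGraph, i: int, sigma_phi: float
) -> tuple[float, float]:
    """Full conditional moments of phi_i given the rest of the field.

    Returns ``(mean, variance)`` with mean the neighbour average and variance
    ``sigma_phi**2 / n_i``.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (graph.n_areas,):
        raise ValueError(f"phi must have length {graph.n_areas}")
    if not 0 <= i < graph.n_areas:
        raise IndexError(f"area index {i} outside 0..{graph.n_areas - 1}")
    if sigma_phi <= 0:
        raise ValueError("sigma_phi must be positive")
    nb = list(graph.neighbors[i])
    mean = float(phi[nb].mean())
    var = sigma_phi**2 / graph.n_i[i]
    return mean, float(var)


def icar_quadform(phi: np.ndarray, graph: AreaGraph) -> float:
    """Pairwise-difference sum ``sum_{i<j, i~j} (phi_i - phi_j)^2``."""
    phi = np.asarray(phi, dtype=float)
    d = phi[graph.edges[:, 0]] - phi[graph.edges[:, 1]]
    return float(d @ d)


def icar_logpdf_unnorm(phi: np.ndarray, graph: AreaGraph, sigma_phi: float) -> float:
    """Unnormalised ICAR log density (joint pairwise-difference form).

    Invariant to adding a constant to ``phi``; the normalising constant
    (which does depend on ``sigma_phi``) is handled where needed by the
    ``-(n-1) log sigma_phi`` rank term in the model's log posterior.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (graph.n_areas,):
        raise ValueError(f"phi must have length {graph.n_areas}")
    if sigma_phi <= 0:
        raise ValueError("sigma_phi must be positive")
    return -icar_quadform(phi, graph) / (2.0 * sigma_phi**2)


def icar_sample(
    graph: AreaGraph,
    sigma_phi: float,
    seed: int | np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Exact draws from the sum-to-zero-constrained ICAR distribution.

    Sampling is done in the eigenbasis of the graph Laplacian: with
    eigenpairs ``(lam_k, v_k)`` excluding the null space, a draw is
    ``sigma_phi * sum_k z_k v_k / sqrt(lam_k)`` with iid standard-normal
    ``z_k``.  Each returned vector is explicitly re-centred to mean zero.

    Returns shape ``(n_areas,)`` when ``size == 1``, else ``(size, n_areas)``.
    """
    if sigma_phi <= 0:
        raise ValueError("sigma_phi must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam, vec = graph._eigenbasis()
    z = rng.standard_normal((size, lam.size))
    draws = (z / np.sqrt(lam)) @ vec.T * sigma_phi
    draws -= draws.mean(axis=1, keepdims=True)
    return draws[0] if size == 1 else draws
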