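"""Minimum-cost closed set segmentation via s-t min-cut.

The ray lattice becomes a directed graph whose minimum-cost *closed* set
(a set containing, with every node, everything the infinite arcs point
to) is exactly the best feasible segmentation:

* ``A_z`` arcs (r, z) -> (r, z-1), capacity "infinity": a retained node
  drags every deeper node on its ray in, so the retained set is a solid
  star-shaped region around the seed and its upper envelope is the
  surface.
* ``A_r`` arcs (r, z) -> (r', max(0, z - delta_r)) for each adjacent ray
  pair, both directions: the boundary indices of neighboring rays cannot
  differ by more than ``delta_r``; 0 forces a sphere, larger values allow
  bumpier surfaces.
* Terminal arcs carry the telescoped node weights
  ``w(r, 0) = c(r, 0)``, ``w(r, z) = c(r, z) - c(r, z-1)``: prefix sums
  of w along a ray reproduce c, so the closed set's total terminal weight
  equals the cost of its surface nodes.  Negative w becomes a source arc
  of capacity -w, nonnegative w a sink arc of capacity w — the standard
  reduction of minimum-cost closed set to min-cut.
* Base arcs s -> (r, 0), capacity "infinity", force a non-empty result
  containing the innermost layer (the seed is inside the object by
  assumption; without these the empty set would be a trivial optimum).

The min-cut itself is solved with :func:`scipy.sparse.csgraph.maximum_flow`
on int64 capacities; float weights are embedded by fixed-point scaling
(see :data:`CAPACITY_BUDGET`).  "Infinite" capacities are a finite BIG
constant larger than the sum of all finite capacities, which provably can
never saturate.  Among equal-cost optima we return the MAXIMAL minimum
closed set (a node is retained unless the sink is still reachable from it
through unsaturated arcs): on cost plateaus — homogeneous object
interiors — this places the boundary at the outermost optimal layer,
i.e. the object's full extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .errors import ParameterError, SizeError
from .rays import CostField
from .template import SphericalTemplate

__all__ = [
    "NodeWeights",
    "SegGraph",
    "CutSurface",
    "node_weights",
    "build_graph",
    "min_cut_surface",
    "brute_force_surface",
]

#: Fixed-point budget: scipy's max-flow solver works in 32-bit integers,
#: so the sum of all scaled finite capacities (and hence BIG and the flow
#: value) must stay below 2**31.  Weights are scaled so that the sum of
#: their magnitudes lands at BUDGET / 4, which bounds the quantization
#: error of the *total* cost by about 2**-28 of the weight-magnitude sum.
CAPACITY_BUDGET = float(2**30)


@dataclass(frozen=True)
class NodeWeights:
    """Telescoped terminal weights; prefix sums along a ray recover c."""

    w: np.ndarray

    @property
    def n_rays(self) -> int:
        return self.w.shape[0]

    @property
    def n_samples(self) -> int:
        return self.w.shape[1]


@dataclass(frozen=True)
class SegGraph:
    """The s-t graph: capacity matrix plus the metadata to interpret it.

    Node ids: ``(r, z) -> r * Z + z``; source ``R*Z``; sink ``R*Z + 1``.
    """

    capacities: csr_matrix
    template: SphericalTemplate
    n_samples: int
    delta_r: int
    scale: float

    @property
    def n_rays(self) -> int:
        return self.template.n_rays

    @property
    def source(self) -> int:
        return self.n_rays * self.n_samples

    @property
    def sink(self) -> int:
        return self.n_rays * self.n_samples + 1


@dataclass(frozen=True)
class CutSurface:
    """Per-ray boundary indices k (each in [0, Z-1]) and the surface cost."""

    k: np.ndarray
    total_cost: float

    def is_feasible(self, template: SphericalTemplate, delta_r: int) -> bool:
        """Check |k_r - k_r'| <= delta_r over all neighbor pairs."""
        return all(
            abs(int(self.k[a]) - int(self.k[b])) <= delta_r
            for a, b in template.neighbor_pairs
        )


def node_weights(costs: CostField) -> NodeWeights:
    """Telescope the cost field into terminal weights.

    ``w(r, 0) = c(r, 0)`` and ``w(r, z) = c(r, z) - c(r, z-1)`` for
    z >= 1, so that ``sum_{z<=k} w(r, z) = c(r, k)``.
    """
    c = costs.c
    w = np.empty_like(c)
    w[:, 0] = c[:, 0]
    w[:, 1:] = np.diff(c, axis=1)
    return NodeWeights(w=w)


def build_graph(
    weights: NodeWeights, template: SphericalTemplate, delta_r: int
) -> SegGraph:
    """Assemble the capacity matrix from weights, adjacency and delta_r."""
    if delta_r < 0:
        raise ParameterError(f"delta_r must be nonnegative, got {delta_r}")
    R, Z = weights.n_rays, weights.n_samples
    if R != template.n_rays:
        raise ParameterError(
            f"weights have {R} rays but template has {template.n_rays}"
        )
    w = weights.w
    s, t = R * Z, R * Z + 1

    sum_abs = float(np.abs(w).sum())
    # Leave headroom: scaled finite capacities sum to <= BUDGET / 4.
    scale = CAPACITY_BUDGET / (4.0 * max(sum_abs, 1.0))
    w_int = np.rint(w * scale).astype(np.int64)
    big = int(np.abs(w_int).sum()) + 1

    node = np.arange(R * Z).reshape(R, Z)

    rows, cols, caps = [], [], []

    # A_z: (r, z) -> (r, z-1), z >= 1
    rows.append(node[:, 1:].ravel())
    cols.append(node[:, :-1].ravel())
    caps.append(np.full(R * (Z - 1), big, dtype=np.int64))

    # A_r: (r, z) -> (r', max(0, z - delta_r)), both directions per pair
    if template.neighbor_pairs:
        pairs = np.array(sorted(template.neighbor_pairs), dtype=np.int64)
        z = np.arange(Z)
        z_tgt = np.maximum(0, z - delta_r)
        for a, b in ((pairs[:, 0], pairs[:, 1]), (pairs[:, 1], pairs[:, 0])):
            rows.append(node[a][:, z].ravel())
            cols.append(node[b][:, z_tgt].ravel())
            caps.append(np.full(len(a) * Z, big, dtype=np.int64))

    # Base arcs s -> (r, 0)
    rows.append(np.full(R, s, dtype=np.int64))
    cols.append(node[:, 0])
    caps.append(np.full(R, big, dtype=np.int64))

    # Terminal arcs from the sign split of w
    flat_w = w_int.ravel()
    neg = flat_w < 0
    pos = ~neg
    ids = node.ravel()
    rows.append(np.full(int(neg.sum()), s, dtype=np.int64))
    cols.append(ids[neg])
    caps.append(-flat_w[neg])
    rows.append(ids[pos])
    cols.append(np.full(int(pos.sum()), t, dtype=np.int64))
    caps.append(flat_w[pos])

    capacities = csr_matrix(
        (np.concatenate(caps), (np.concatenate(rows), np.concatenate(cols))),
        shape=(R * Z + 2, R * Z + 2),
        dtype=np.int64,
    )
    assert big <= np.iinfo(np.int32).max, "capacity budget exceeded"
    capacities = capacities.astype(np.int32)
    return SegGraph(
        capacities=capacities,
        template=template,
        n_samples=Z,
        delta_r=int(delta_r),
        scale=scale,
    )


def min_cut_surface(graph: SegGraph, costs: CostField) -> CutSurface:
    """Solve the min-cut and read off the per-ray boundary indices.

    The retained set is the maximal minimum-cut source side: after
    max-flow, a node is dropped only if the sink is still reachable from
    it through arcs with residual capacity.  ``k_r`` is the outermost
    retained layer of ray r; the total cost is recomputed exactly from
    the float cost field.
    """
    R, Z = graph.n_rays, graph.n_samples
    result = maximum_flow(graph.capacities, graph.source, graph.sink)
    residual = graph.capacities - result.flow
    residual.eliminate_zeros()
    # Nodes that can reach t in the residual graph = reverse BFS from t.
    reach_t = breadth_first_order(
        residual.T, graph.sink, directed=True, return_predecessors=False
    )
    retained = np.ones(R * Z + 2, dtype=bool)
    retained[reach_t] = False

    per_ray = retained[: R * Z].reshape(R, Z)
    # Closure along A_z guarantees each ray's retained set is a prefix.
    k = per_ray.sum(axis=1).astype(np.int64) - 1
    if np.any(k < 0):  # pragma: no cover - excluded by the base arcs
        raise RuntimeError("base layer escaped the closed set")
    total = float(costs.c[np.arange(R), k].sum())
    return CutSurface(k=k, total_cost=total)


def _independent_minima(c: np.ndarray) -> CutSurface:
    """Per-ray minima, largest index on ties (vacuous constraint case)."""
    rev_argmin = c.shape[1] - 1 - np.argmin(c[:, ::-1], axis=1)
    total = float(c[np.arange(c.shape[0]), rev_argmin].sum())
    return CutSurface(k=rev_argmin.astype(np.int64), total_cost=total)


def brute_force_surface(
    costs: CostField, template: SphericalTemplate, delta_r: int
) -> CutSurface:
    """Exhaustive-search oracle for small instances.

    Depth-first search over per-ray boundary indices in ray order with
    interval constraint propagation (assigning ray r to layer k bounds
    every other ray r' to ``k ± dist(r, r') * delta_r``) and admissible
    bound pruning (partial cost plus the sum of per-ray minima over the
    still-allowed layers).  Exact: explores every assignment not provably
    dominated.  Ties are broken toward the lexicographically largest k.

    Raises
    ------
    SizeError
        If the worst-case constrained search space exceeds ~1e9 states.
    """
    if delta_r < 0:
        raise ParameterError(f"delta_r must be nonnegative, got {delta_r}")
    c = costs.c
    R, Z = c.shape
    if R != template.n_rays:
        raise ParameterError("cost field and template disagree on R")

    if delta_r >= Z - 1:
        return _independent_minima(c)

    branching = 2 * min(delta_r, Z - 1) + 1
    if Z * branching ** max(R - 1, 0) > 1e9:
        raise SizeError(
            f"instance too large for exhaustive search (R={R}, Z={Z}, delta_r={delta_r})"
        )

    # All-pairs hop distances on the ray adjacency, for propagation.
    from scipy.sparse.csgraph import shortest_path

    adj = np.zeros((R, R))
    for a, b in template.neighbor_pairs:
        adj[a, b] = adj[b, a] = 1
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True)
    spread = (dist * delta_r).astype(np.int64)  # max |k_r - k_r'| allowed

    best_cost = np.inf
    best_k: np.ndarray | None = None
    lo = np.zeros(R, dtype=np.int64)
    hi = np.full(R, Z - 1, dtype=np.int64)
    k = np.zeros(R, dtype=np.int64)

    def remaining_bound(r: int, lo_: np.ndarray, hi_: np.ndarray) -> float:
        return sum(
            float(c[q, lo_[q] : hi_[q] + 1].min()) for q in range(r, R)
        )

    def dfs(r: int, partial: float, lo_: np.ndarray, hi_: np.ndarray):
        nonlocal best_cost, best_k
        if r == R:
            if partial < best_cost - 1e-15:
                best_cost = partial
                best_k = k.copy()
            return
        if partial + remaining_bound(r, lo_, hi_) >= best_cost - 1e-15:
            return
        # Descending layer order => first optimum found is lexicographically
        # largest among ties (strict improvement required thereafter).
        for kr in range(hi_[r], lo_[r] - 1, -1):
            new_lo = np.maximum(lo_, kr - spread[r])
            new_hi = np.minimum(hi_, kr + spread[r])
            if np.any(new_lo[r + 1 :] > new_hi[r + 1 :]):
                continue
            k[r] = kr
            dfs(r + 1, partial + float(c[r, kr]), new_lo, new_hi)

    dfs(0, 0.0, lo, hi)
    assert best_k is not None
    return CutSurface(k=best_k, total_cost=float(best_cost))
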