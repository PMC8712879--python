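"""Right-sided His-Purkinje surrogate for the LBBB activation mode.

In left bundle branch block only the right bundle conducts: a ~40 mm trunk
runs from a septal origin to the RV apex and then arborizes over the RV
endocardium.  The tree conducts at 3 mm/ms and couples to working myocardium
only at its terminal Purkinje-myocardial junctions (PMJs), whose onset times
(path length from origin / conduction velocity) become the Eikonal boundary
conditions.  The left-sided tree is absent by construction.

The arborization is a deterministic fractal surrogate grown on the RV
endocardial surface graph: the published description anchors only the trunk
length and the conduction velocity, so branch length, branching angle and
generation count are declared, seeded parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .anatomy import VentricularMesh

logger = logging.getLogger(__name__)


@dataclass
class PurkinjeTree:
    """Directed conduction tree with terminal myocardial junctions.

    ``parent`` maps each tree node (a mesh node index) to its predecessor
    and the connecting edge length in mm; ``pmjs`` holds terminal
    (mesh node, onset ms) couplings.
    """

    origin: int
    parent: dict[int, tuple[int, float]] = field(default_factory=dict)
    pmjs: list[tuple[int, float]] = field(default_factory=list)
    velocity: float = 3.0  # mm/ms, His-Purkinje conduction speed

    def path_length(self, node: int) -> float:
        """Cumulative tree path length (mm) from the origin to ``node``."""
        length = 0.0
        while node != self.origin:
            node, edge = self.parent[node]
            length += edge
        return length

    @property
    def nodes(self) -> list[int]:
        return [self.origin] + list(self.parent.keys())


@dataclass(frozen=True)
class PurkinjeParams:
    bundle_length: float = 40.0   # mm, right bundle trunk
    branch_length: float = 8.0    # mm per generation
    branch_angle: float = 20.0    # degrees off the parent direction
    generations: int = 6          # full binary tree -> up to 2**6 PMJs
    velocity: float = 3.0         # mm/ms


def _surface_graph(mesh: VentricularMesh, surf: np.ndarray):
    """Edge graph restricted to the RV endocardial node set."""
    on_surf = np.zeros(mesh.n_nodes, dtype=bool)
    on_surf[surf] = True
    pairs = []
    t = mesh.tets
    for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
        i, j = t[:, a], t[:, b]
        sel = on_surf[i] & on_surf[j]
        pairs.append(np.column_stack([i[sel], j[sel]]))
    pairs = np.unique(np.sort(np.concatenate(pairs), axis=1), axis=0)
    w = np.linalg.norm(mesh.nodes[pairs[:, 0]] - mesh.nodes[pairs[:, 1]], axis=1)
    n = mesh.n_nodes
    g = csr_matrix((np.concatenate([w, w]),
                    (np.concatenate([pairs[:, 0], pairs[:, 1]]),
                     np.concatenate([pairs[:, 1], pairs[:, 0]]))), shape=(n, n))
    return g, pairs


def _neighbors(pairs: np.ndarray, n: int):
    adj: dict[int, list[int]] = {}
    for i, j in pairs:
        adj.setdefault(int(i), []).append(int(j))
        adj.setdefault(int(j), []).append(int(i))
    return adj


def grow_rv_tree(mesh: VentricularMesh,
                 params: PurkinjeParams | None = None,
                 seed: int = 0) -> PurkinjeTree:
    """Grow the RV conduction tree: septal origin -> ~40 mm trunk toward the
    RV apex -> recursive binary branching on the endocardial surface.

    Terminal tips become PMJs with onset = path length / velocity.  Tips that
    land on scar-only nodes are discarded with a warning.  Deterministic for
    a fixed seed.
    """
    if params is None:
        params = PurkinjeParams()
    surf = mesh.endo_surface_RV
    if surf.size == 0:
        raise ValueError("mesh has no RV endocardial surface")
    rng = np.random.default_rng(seed)
    graph, pairs = _surface_graph(mesh, surf)
    adj = _neighbors(pairs, mesh.n_nodes)
    pts = mesh.nodes
    scar_node = mesh.node_is_scar()

    # origin: RV endo node closest to the basal septum (the His entry point)
    if mesh.shape is not None:
        target = np.array([mesh.shape.lv_epi_radii[0], 0.0, -5.0])
    else:
        target = pts[surf].mean(axis=0) + np.array([0.0, 0.0, 20.0])
    origin = int(surf[np.argmin(np.linalg.norm(pts[surf] - target, axis=1))])
    apex = int(surf[np.argmin(pts[surf, 2])])

    dist, pred = dijkstra(graph, directed=False, indices=origin,
                          return_predecessors=True)
    if not np.isfinite(dist[apex]):
        raise ValueError("RV apex unreachable on the endocardial surface")
    # trunk: shortest surface path origin -> apex, truncated at bundle_length
    path = [apex]
    while path[-1] != origin:
        path.append(int(pred[path[-1]]))
    path = path[::-1]
    tree = PurkinjeTree(origin=origin, velocity=params.velocity)
    trunk_len = 0.0
    trunk_end = origin
    for a, b in zip(path[:-1], path[1:]):
        step = float(np.linalg.norm(pts[b] - pts[a]))
        if trunk_len + step > params.bundle_length and trunk_end != origin:
            break
        if b not in tree.parent:
            tree.parent[b] = (a, step)
        trunk_len += step
        trunk_end = b

    # recursive surface branching from the trunk end
    d0 = pts[trunk_end] - pts[path[max(0, path.index(trunk_end) - 1)]]
    nrm = np.linalg.norm(d0)
    d0 = d0 / nrm if nrm > 0 else np.array([0.0, 0.0, -1.0])
    visited = set(tree.parent) | {origin}
    tips: list[int] = []

    def surface_normal(node: int) -> np.ndarray:
        nbrs = adj.get(node, [])
        if len(nbrs) < 2:
            return np.array([0.0, 0.0, 1.0])
        rel = pts[nbrs] - pts[node]
        # smallest principal direction of the neighbor cloud
        _, _, vt = np.linalg.svd(rel, full_matrices=False)
        return vt[-1]

    def walk(start: int, direction: np.ndarray, length: float) -> int | None:
        cur = start
        travelled = 0.0
        d = direction.copy()
        while travelled < length:
            cands = [c for c in adj.get(cur, []) if c not in visited]
            if not cands:
                return cur if cur != start else None
            steps = pts[cands] - pts[cur]
            ln = np.linalg.norm(steps, axis=1)
            cos = (steps / ln[:, None]) @ d
            k = int(np.argmax(cos + 1e-9 * rng.random(len(cands))))
            if cos[k] < -0.5:
                return cur if cur != start else None
            nxt = cands[k]
            tree.parent[nxt] = (cur, float(ln[k]))
            visited.add(nxt)
            travelled += float(ln[k])
            d = 0.7 * d + 0.3 * steps[k] / ln[k]
            d /= np.linalg.norm(d)
            cur = nxt
        return cur

    def branch(node: int, direction: np.ndarray, gen: int) -> None:
        if gen == 0:
            tips.append(node)
            return
        nrm = surface_normal(node)
        t = direction - nrm * (direction @ nrm)
        tl = np.linalg.norm(t)
        t = t / tl if tl > 1e-9 else direction
        ang = np.radians(params.branch_angle)
        for sgn in (+1.0, -1.0):
            d = np.cos(ang) * t + sgn * np.sin(ang) * np.cross(nrm, t)
            d /= np.linalg.norm(d)
            end = walk(node, d, params.branch_length)
            if end is None:
                tips.append(node)
                continue
            branch(end, d, gen - 1)

    branch(trunk_end, d0, params.generations)

    n_discard = 0
    seen: dict[int, float] = {}
    for tip in tips:
        if scar_node[tip]:
            n_discard += 1
            continue
        onset = tree.path_length(tip) / params.velocity
        if tip not in seen or onset < seen[tip]:
            seen[tip] = onset
    if n_discard:
        logger.warning("%d PMJ tip(s) on scar discarded", n_discard)
    tree.pmjs = sorted(seen.items())
    if not tree.pmjs:
        raise ValueError("tree produced no usable PMJs")
    return tree


def lbbb_sources(tree: PurkinjeTree) -> list[tuple[int, float]]:
    """Eikonal boundary conditions for the LBBB mode: the PMJ couplings.

    The His-Purkinje system is insulated from working myocardium everywhere
    except at the fiber ends, so the source list is exactly the PMJ set.
    """
    if not tree.pmjs:
        raise ValueError("tree has no PMJs")
    return list(tree.pmjs)
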