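"""Anisotropic first-arrival activation on tetrahedral meshes.

The activation time field is computed as the shortest travel time on a graph
built from the mesh edges, where an edge with vector e inside an element with
fiber f costs the Riemannian travel time

    t(e) = sqrt(e' D^-1 e),   D = v_f^2 f f' + v_t^2 (I - f f'),

with v_f the along-fiber and v_t the cross-fiber speed; shortest graph paths
converge (from above) to the continuum anisotropic Eikonal solution.  Speeds
derive from a global conductivity scale ``g`` via v = v0 * sqrt(g * scale):
a 4:1 conductivity ratio along:across fibers therefore yields a 2:1 velocity
ratio, and fibrosis at 1% conductivity propagates at 10% of normal speed.
Scar is inexcitable and removed from the propagation graph.

The default solver is two-stage: the Dijkstra graph pass (by itself the pure
graph-relaxation solution, exactly checkable against a shortest-path oracle)
followed by source-factored locally-exact face updates that remove both the
angular metrication error of the edge graph and the wavefront-curvature
error of plain linear local solvers; on a homogeneous 2 mm mesh the result
matches the elliptical-norm closed form to well under 0.1%.

The graph can optionally be augmented with second-ring "virtual" edges in
tissue-homogeneous, scar-free neighborhoods (``order=2``), which tightens
the pure graph stage when refinement is disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .anatomy import TISSUE_FIBROSIS, TISSUE_SCAR, WALL_RV_FREE, VentricularMesh

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConductionModel:
    """Tissue conduction parameters.

    Parameters
    ----------
    g : dimensionless global conductivity scale (the personalized parameter).
    v0 : along-fiber speed at g = 1, mm/ms.
    anisotropy_ratio : conductivity ratio along:across fibers (4 -> 2:1 speed).
    fibrosis_fraction : conductivity of fibrotic tissue relative to normal.
    """

    g: float = 1.0
    v0: float = 0.6
    anisotropy_ratio: float = 4.0
    fibrosis_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.g <= 0 or self.v0 <= 0:
            raise ValueError("g and v0 must be positive")
        if self.anisotropy_ratio < 1:
            raise ValueError("anisotropy_ratio must be >= 1")

    def element_speeds(self, mesh: VentricularMesh):
        """(v_f, v_t) per element; NaN on scar elements."""
        scale = np.ones(mesh.n_elements)
        scale[mesh.tissue_class == TISSUE_FIBROSIS] = self.fibrosis_fraction
        scale[mesh.tissue_class == TISSUE_SCAR] = np.nan
        v_f = self.v0 * np.sqrt(self.g * scale)
        v_t = v_f / np.sqrt(self.anisotropy_ratio)
        return v_f, v_t


@dataclass
class ActivationMap:
    """Per-node first-arrival activation time for one pacing mode.

    ``at`` is in ms with ``np.inf`` on nodes isolated by scar.
    """

    at: np.ndarray
    sources: list[tuple[int, float]]
    mode: str = ""

    @property
    def finite(self) -> np.ndarray:
        return np.isfinite(self.at)

    @property
    def at_min(self) -> float:
        return float(np.min(self.at[self.finite]))

    @property
    def at_max(self) -> float:
        return float(np.max(self.at[self.finite]))


def _directional_speed(u: np.ndarray, f: np.ndarray, v_f: np.ndarray,
                       v_t: np.ndarray) -> np.ndarray:
    """Ray (group) speed of the anisotropic front along unit direction u.

    The first-arrival time between points separated by x in a homogeneous
    medium is the elliptical norm sqrt(x' D^-1 x) with
    D = v_f^2 f f' + v_t^2 (I - f f'), so the speed along u is
    1 / sqrt((u.f)^2 / v_f^2 + (1 - (u.f)^2) / v_t^2).  Along fibers this is
    v_f, across them v_t, reproducing the 2:1 speed ratio at 4:1 conductivity.
    """
    c2 = np.einsum("ij,ij->i", u, f) ** 2
    return 1.0 / np.sqrt(c2 / v_f ** 2 + (1.0 - c2) / v_t ** 2)


_TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def build_propagation_graph(mesh: VentricularMesh, model: ConductionModel,
                            order: int = 1) -> csr_matrix:
    """Symmetric sparse matrix of edge travel times (ms).

    Order-1 edges are the tetrahedral edges of non-scar elements; each takes
    the slowest incident element's directional speed, so the graph time is a
    true upper bound on the continuum travel time even where an edge skirts
    slow tissue — thin fibrotic layers genuinely impede crossing instead of
    being tunnelled through, and the refinement stage (which only lowers
    times) starts from a valid bound.  Order-2 edges connect second-ring
    node pairs whose combined incident elements are all non-scar and of a
    single tissue class, again at the slowest incident directional speed.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    v_f, v_t = model.element_speeds(mesh)
    keep = mesh.tissue_class != TISSUE_SCAR
    tets = mesh.tets[keep]
    vf_k, vt_k = v_f[keep], v_t[keep]
    fib_k = mesh.fiber[keep]
    n = mesh.n_nodes

    ii, jj, ww = [], [], []
    for a, b in _TET_EDGES:
        i, j = tets[:, a], tets[:, b]
        d = mesh.nodes[j] - mesh.nodes[i]
        length = np.linalg.norm(d, axis=1)
        u = d / length[:, None]
        v = _directional_speed(u, fib_k, vf_k, vt_k)
        ii.append(np.minimum(i, j))
        jj.append(np.maximum(i, j))
        ww.append(length / v)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    ww = np.concatenate(ww)
    # duplicate edges (shared by several elements): keep the slowest
    # (max time) so the edge cannot shortcut through faster neighbours
    key = ii.astype(np.int64) * n + jj
    orderk = np.argsort(key, kind="stable")
    key_s, ii_s, jj_s, ww_s = key[orderk], ii[orderk], jj[orderk], ww[orderk]
    first = np.ones(len(key_s), dtype=bool)
    first[1:] = key_s[1:] != key_s[:-1]
    starts = np.flatnonzero(first)
    w_edge = np.maximum.reduceat(ww_s, starts)
    e_i, e_j = ii_s[first], jj_s[first]

    rows = [e_i]
    cols = [e_j]
    wts = [w_edge]

    if order == 2:
        i2, j2, w2 = _second_ring_edges(mesh, v_f, v_t, e_i, e_j)
        if len(i2):
            rows.append(i2)
            cols.append(j2)
            wts.append(w2)

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    w = np.concatenate(wts)
    return _sym_min(r, c, w, n)


def _sym_min(r, c, w, n) -> csr_matrix:
    """Symmetric CSR where duplicate entries take the minimum weight."""
    rr = np.concatenate([r, c])
    cc = np.concatenate([c, r])
    ww = np.concatenate([w, w])
    key = rr.astype(np.int64) * n + cc
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    first = np.ones(len(key_s), dtype=bool)
    first[1:] = key_s[1:] != key_s[:-1]
    starts = np.flatnonzero(first)
    w_min = np.minimum.reduceat(ww[order], starts)
    return csr_matrix((w_min, (rr[order][first], cc[order][first])),
                      shape=(n, n))


def _second_ring_edges(mesh: VentricularMesh, v_f, v_t, e_i, e_j):
    """Candidate virtual edges between second-ring node pairs."""
    n = mesh.n_nodes
    m = mesh.n_elements
    adj = csr_matrix((np.ones(len(e_i), dtype=np.int8), (e_i, e_j)),
                     shape=(n, n))
    adj = adj + adj.T
    a2 = (adj @ adj).tocoo()
    cand = (a2.row < a2.col)
    r2, c2 = a2.row[cand], a2.col[cand]
    # drop pairs already joined by a mesh edge
    direct = adj.tocsr()
    has_direct = np.asarray(direct[r2, c2]).ravel() > 0
    r2, c2 = r2[~has_direct], c2[~has_direct]
    if len(r2) == 0:
        return np.array([], int), np.array([], int), np.array([], float)

    # node -> incident elements (CSR)
    elem_ids = np.repeat(np.arange(m), 4)
    inc = csr_matrix((np.ones(4 * m, dtype=np.int8),
                      (mesh.tets.ravel(), elem_ids)), shape=(n, m))
    node_scar_touch = np.asarray(
        inc @ (mesh.tissue_class == TISSUE_SCAR).astype(np.int8)).ravel() > 0
    node_fib_touch = np.asarray(
        inc @ (mesh.tissue_class == TISSUE_FIBROSIS).astype(np.int8)).ravel() > 0
    node_norm_touch = np.asarray(
        inc @ (mesh.tissue_class == 0).astype(np.int8)).ravel() > 0
    homogeneous = ~node_scar_touch & ~(node_fib_touch & node_norm_touch)
    ok = homogeneous[r2] & homogeneous[c2] & (node_fib_touch[r2] == node_fib_touch[c2])
    r2, c2 = r2[ok], c2[ok]
    if len(r2) == 0:
        return np.array([], int), np.array([], int), np.array([], float)

    d = mesh.nodes[c2] - mesh.nodes[r2]
    length = np.linalg.norm(d, axis=1)
    u = d / length[:, None]

    # minimum directional speed over elements incident to either endpoint
    indptr, indices = inc.indptr, inc.indices
    counts = np.diff(indptr)
    speed = np.full(len(r2), np.inf)
    for endpoints in (r2, c2):
        reps = counts[endpoints]
        total = int(reps.sum())
        edge_of = np.repeat(np.arange(len(r2)), reps)
        starts = np.repeat(indptr[endpoints], reps)
        offset = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
        gather = indices[starts + offset]
        ue = u[edge_of]
        ve = _directional_speed(ue, mesh.fiber[gather], v_f[gather], v_t[gather])
        np.minimum.at(speed, edge_of, ve)
    return r2, c2, length / speed


def solve_activation(mesh: VentricularMesh, model: ConductionModel,
                     sources: list[tuple[int, float]], order: int = 1,
                     refine: bool = True, mode: str = "",
                     graph: csr_matrix | None = None) -> ActivationMap:
    """First-arrival activation times from onset-time boundary conditions.

    ``sources`` is a list of (node index, onset ms) pairs; the earliest
    arrival over all sources defines each node's activation time.  Nodes in
    scar-isolated components keep ``np.inf`` (with a warning).

    Two stages: a Dijkstra pass on the tet-edge graph (an upper bound, and
    by itself exactly the graph-relaxation solution — ``refine=False``),
    then locally-exact tetrahedral face updates that converge to the
    continuum anisotropic Eikonal solution.
    """
    if not sources:
        raise ValueError("at least one source is required")
    scar_node = mesh.node_is_scar()
    src_nodes = [s for s, _ in sources]
    if all(scar_node[s] for s in src_nodes):
        raise ValueError("all sources lie on scar tissue")
    live = [(s, t0) for s, t0 in sources if not scar_node[s]]
    if len(live) < len(sources):
        logger.warning("%d source(s) on scar discarded", len(sources) - len(live))
    if graph is None:
        graph = build_propagation_graph(mesh, model, order=order)
    idx = np.array([s for s, _ in live])
    onsets = np.array([t0 for _, t0 in live])
    if refine:
        at, src_ord = multi_source_times(graph, idx, onsets,
                                         return_sources=True)
        at = refine_activation(mesh, model, at,
                               src_xyz=mesh.nodes[idx[src_ord]],
                               src_onset=onsets[src_ord])
    else:
        at = multi_source_times(graph, idx, onsets)
    n_inf = int(np.sum(~np.isfinite(at) & ~scar_node))
    if n_inf:
        logger.warning("%d non-scar node(s) unreachable from sources", n_inf)
    return ActivationMap(at=at, sources=list(sources), mode=mode)


def multi_source_times(graph: csr_matrix, idx: np.ndarray,
                       onsets: np.ndarray, return_sources: bool = False):
    """First-arrival times over all sources via one virtual-source Dijkstra.

    One virtual node per source is appended with a directed edge of weight =
    onset time to its source node, so the cost is a single multi-source
    shortest-path sweep.  Zero onsets are nudged to a denormal positive
    weight because the CSR format drops explicit zeros.

    With ``return_sources`` the index (into ``idx``) of the source winning
    each node is returned as well.
    """
    from scipy.sparse import bmat

    n = graph.shape[0]
    s = len(idx)
    row = csr_matrix((np.maximum(onsets, 1e-300),
                      (np.arange(s), idx)), shape=(s, n))
    aug = bmat([[graph, None], [row, None]], format="csr")
    aug.resize((n + s, n + s))
    virt = np.arange(n, n + s)
    dist, _, winner = dijkstra(aug, directed=True, indices=virt,
                               min_only=True, return_predecessors=True)
    if not return_sources:
        return dist[:n]
    src_ord = winner[:n] - n
    src_ord[src_ord < 0] = 0  # unreachable nodes: arbitrary (stay inf)
    return dist[:n], src_ord


def geodesic_distance(mesh: VentricularMesh, from_node: int,
                      to_region, include_scar: bool = True,
                      order: int = 1) -> float:
    """Ruler-like distance (mm): isotropic unit-speed first arrival from
    ``from_node``, minimized over ``to_region``.

    Scar elements are part of the domain by default — the distance mimics a
    measurement taken directly on CT/MRI images with a ruler.
    """
    to_region = np.atleast_1d(np.asarray(to_region, dtype=int))
    if to_region.size == 0:
        raise ValueError("to_region is empty")
    field = geodesic_field(mesh, from_node, include_scar=include_scar,
                           order=order)
    return float(np.min(field[to_region]))


def geodesic_field(mesh: VentricularMesh, from_node: int,
                   include_scar: bool = True, order: int = 1) -> np.ndarray:
    """Isotropic unit-speed distance field (mm) from one node."""
    if mesh.node_is_scar()[from_node] and not include_scar:
        raise ValueError("from_node lies on scar")
    work = mesh
    if include_scar:
        # treat every element as normal tissue for the ruler metric
        import copy
        work = copy.copy(mesh)
        work.tissue_class = np.zeros(mesh.n_elements, dtype=np.int32)
    iso = ConductionModel(g=1.0, v0=1.0, anisotropy_ratio=1.0)
    graph = build_propagation_graph(work, iso, order=order)
    return dijkstra(graph, directed=False, indices=from_node)


def late_activation_zone(amap: ActivationMap, mesh: VentricularMesh,
                         fraction: float = 0.9) -> np.ndarray:
    """Nodes activating in the last (1 - fraction) of the activation span,
    restricted to the LV (free wall + septum).

    The latest-activated region is the conventional target for the LV lead.
    With a degenerate span (uniform activation) all finite LV nodes qualify.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    finite = amap.finite
    if not np.any(finite):
        raise ValueError("activation map has no finite nodes")
    lo, hi = amap.at_min, amap.at_max
    thr = lo + fraction * (hi - lo)
    in_lv = mesh.wall_label_node != WALL_RV_FREE
    return np.flatnonzero(finite & in_lv & (amap.at >= thr))


# ---------------------------------------------------------------------------
# locally-exact tetrahedral refinement
# ---------------------------------------------------------------------------

def _element_metric(mesh: VentricularMesh, model: ConductionModel) -> np.ndarray:
    """Inverse speed tensor M = D^-1 per element (ms^2/mm^2); NaN on scar."""
    v_f, v_t = model.element_speeds(mesh)
    f = mesh.fiber
    eye = np.eye(3)
    coef = 1.0 / v_f ** 2 - 1.0 / v_t ** 2
    return (coef[:, None, None] * np.einsum("ij,ik->ijk", f, f)
            + (1.0 / v_t ** 2)[:, None, None] * eye)


def _local_candidates(nodes, tets, M, at, apex_k: int) -> np.ndarray:
    """Arrival-time candidates at each tet's apex node from its opposite
    face: the characteristic enters through the face at the barycentric
    point minimizing interpolated time + metric travel time.  Returns the
    candidate per tet (inf where invalid)."""
    others = [k for k in range(4) if k != apex_k]
    n_idx = tets[:, apex_k]
    a, b, c = (tets[:, k] for k in others)
    xa, xb, xc, xn = nodes[a], nodes[b], nodes[c], nodes[n_idx]
    Ta, Tb, Tc = at[a], at[b], at[c]
    w = xn - xa
    e1, e2 = xb - xa, xc - xa
    g1, g2 = Tb - Ta, Tc - Ta

    Mw = np.einsum("ijk,ik->ij", M, w)
    Me1 = np.einsum("ijk,ik->ij", M, e1)
    Me2 = np.einsum("ijk,ik->ij", M, e2)
    wMw = np.einsum("ij,ij->i", w, Mw)
    A11 = np.einsum("ij,ij->i", e1, Me1)
    A12 = np.einsum("ij,ij->i", e1, Me2)
    A22 = np.einsum("ij,ij->i", e2, Me2)
    b1 = np.einsum("ij,ij->i", e1, Mw)
    b2 = np.einsum("ij,ij->i", e2, Mw)

    det = A11 * A22 - A12 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = (A22 * b1 - A12 * b2) / det
        p2 = (A11 * b2 - A12 * b1) / det
        q1 = (A22 * g1 - A12 * g2) / det
        q2 = (A11 * g2 - A12 * g1) / det
        denom = 1.0 - (g1 * q1 + g2 * q2)
        num = wMw - (b1 * p1 + b2 * p2)
        s = np.sqrt(num / denom)
        l1 = p1 - s * q1
        l2 = p2 - s * q2
        face = Ta + l1 * g1 + l2 * g2 + s
    eps = 1e-12
    with np.errstate(invalid="ignore"):
        ok = (np.isfinite(face) & (denom > 0) & (num >= -eps)
              & (l1 >= -eps) & (l2 >= -eps) & (l1 + l2 <= 1 + eps))
    cand = np.where(ok, face, np.inf)

    # edge and vertex fallbacks of the face
    for (T0, T1, x0, e, Me_, al, be) in (
        (Ta, Tb, xa, e1, Me1, A11, b1),
        (Ta, Tc, xa, e2, Me2, A22, b2),
        (Tb, Tc, xb, xc - xb, None, None, None),
    ):
        w0 = xn - x0
        if Me_ is None:
            Me_ = np.einsum("ijk,ik->ij", M, e)
            al = np.einsum("ij,ij->i", e, Me_)
            be = np.einsum("ij,ij->i", e, np.einsum("ijk,ik->ij", M, w0))
        Mw0 = np.einsum("ijk,ik->ij", M, w0)
        w0Mw0 = np.einsum("ij,ij->i", w0, Mw0)
        ge = T1 - T0
        with np.errstate(divide="ignore", invalid="ignore"):
            s2 = (w0Mw0 - be ** 2 / al) / (1.0 - ge ** 2 / al)
            s_e = np.sqrt(s2)
            t = (be - s_e * ge) / al
            edge_val = T0 + t * ge + s_e
        ok_e = np.isfinite(edge_val) & (t > eps) & (t < 1 - eps) & (s2 >= -eps)
        cand = np.minimum(cand, np.where(ok_e, edge_val, np.inf))
        # vertex endpoints
        v0 = T0 + np.sqrt(w0Mw0)
        we = w0 - e
        v1 = T1 + np.sqrt(np.einsum("ij,ij->i", we,
                                    np.einsum("ijk,ik->ij", M, we)))
        cand = np.minimum(cand, np.minimum(
            np.where(np.isfinite(v0), v0, np.inf),
            np.where(np.isfinite(v1), v1, np.inf)))
    return n_idx, cand


def refine_activation(mesh: VentricularMesh, model: ConductionModel,
                      at: np.ndarray, src_xyz: np.ndarray,
                      src_onset: np.ndarray, tol_mm: float = 6e-3,
                      max_sweeps: int = 300) -> np.ndarray:
    """Tighten a graph first-arrival field with factored local face updates.

    Times are re-expressed relative to a local reference solution
    T0(x) = min_k [onset_k + sqrt((x - s_k)' M (x - s_k))] over the dominant
    sources of the apex and face nodes; tau = T/T0 (not T itself) is
    interpolated linearly over the upwind face, which removes the
    wavefront-curvature error that limits plain linear updates near point
    sources and reproduces planar multi-source fronts exactly.  The
    minimizing entry point on each face is found by sampled search with
    local grid refinements.  Faces where the factorization is ill-posed
    (zero reference time) fall back to the closed-form linear update.

    ``at`` must be an upper bound (the Dijkstra stage); values only
    decrease, and never below the earliest onset.  Active-set Jacobi sweeps
    run until no node improves by more than the tolerance, specified as an
    equivalent front-path length in mm and converted to ms with the model's
    along-fiber speed — a tolerance in time units would break the exact 1/c
    time-scaling of the solution under a c^2 conductivity rescale.
    """
    tol = tol_mm / (model.v0 * np.sqrt(model.g))
    at = at.copy()
    keep = np.flatnonzero(mesh.tissue_class != TISSUE_SCAR)
    tets = mesh.tets[keep]
    M = _element_metric(mesh, model)[keep]
    nodes = mesh.nodes
    n = mesh.n_nodes
    m = len(tets)
    if m == 0:
        return at
    floor = float(np.min(src_onset))

    # candidates: one per (tet, apex) with the opposite face as upwind face
    apex = tets.T.ravel()
    others = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
    face = np.concatenate([tets[:, o] for o in others])  # (4m, 3)
    tid = np.tile(np.arange(m), 4)
    ncand = 4 * m

    # face node -> candidate incidence for the active set
    inc = csr_matrix((np.ones(3 * ncand, dtype=np.int8),
                      (face.ravel(), np.repeat(np.arange(ncand), 3))),
                     shape=(n, ncand)).tocsr()

    lam0 = np.array([(0.0, 0.0), (1.0, 0.0), (0.0, 1.0),
                     (0.5, 0.0), (0.0, 0.5), (0.5, 0.5), (1 / 3, 1 / 3)])
    neigh = np.array([(d1, d2) for d1 in (-1, 0, 1) for d2 in (-1, 0, 1)
                      if (d1, d2) != (0, 0)])

    def minimize_on_faces(sub, t0_of):
        """Sampled barycentric minimization of tau*T0 + travel."""
        A = apex[sub]
        F = face[sub]
        Me = M[tid[sub]]
        xf = nodes[F]                                     # (k, 3, 3)
        xn = nodes[A]
        T0f = np.stack([t0_of(xf[:, i], Me) for i in range(3)], axis=1)
        vals = at[F]
        good = np.all(np.isfinite(vals) & (T0f > 1e-9), axis=1) \
            & np.all(vals > 0, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.where(T0f > 1e-9, vals / np.where(T0f > 1e-9, T0f, 1.0),
                           1.0)

        def objective(l1, l2):
            w0 = 1.0 - l1 - l2
            p = (xf[:, 0] * w0[:, None] + xf[:, 1] * l1[:, None]
                 + xf[:, 2] * l2[:, None])
            tp = tau[:, 0] * w0 + tau[:, 1] * l1 + tau[:, 2] * l2
            dn = xn - p
            trav = np.sqrt(np.einsum("kj,kjl,kl->k", dn, Me, dn))
            return tp * t0_of(p, Me) + trav

        k = len(sub)
        best = np.full(k, np.inf)
        bl1 = np.zeros(k)
        bl2 = np.zeros(k)
        for l1_0, l2_0 in lam0:
            v = objective(np.full(k, l1_0), np.full(k, l2_0))
            better = v < best
            best = np.where(better, v, best)
            bl1 = np.where(better, l1_0, bl1)
            bl2 = np.where(better, l2_0, bl2)
        step = 0.5
        for _r in range(3):
            step /= 3.0
            for d1, d2 in neigh:
                l1 = np.clip(bl1 + d1 * step, 0.0, 1.0)
                l2 = np.clip(bl2 + d2 * step, 0.0, 1.0)
                over = l1 + l2 > 1.0
                l2 = np.where(over, 1.0 - l1, l2)
                v = objective(l1, l2)
                better = v < best
                best = np.where(better, v, best)
                bl1 = np.where(better, l1, bl1)
                bl2 = np.where(better, l2, bl2)
        cand = np.where(good, best, np.inf)
        bad = np.flatnonzero(~good)
        if len(bad):
            vt = np.column_stack([F[bad], A[bad]])
            _, lin = _local_candidates(nodes, vt, Me[bad], at, 3)
            cand[bad] = lin
        return A, cand

    active = np.ones(ncand, dtype=bool)
    for _ in range(max_sweeps):
        sub = np.flatnonzero(active)
        if len(sub) == 0:
            break
        # group by whether the four local nodes share one dominant source;
        # the reference solution T0 then needs one or up to four sources
        local_nodes = np.column_stack([apex[sub], face[sub]])   # (k, 4)
        sxyz = src_xyz[local_nodes]                             # (k, 4, 3)
        sons = src_onset[local_nodes]                           # (k, 4)
        uniform = np.all(
            np.all(sxyz == sxyz[:, :1, :], axis=2) & (sons == sons[:, :1]),
            axis=1)

        new = at.copy()
        for sel, nsrc in ((uniform, 1), (~uniform, 4)):
            ss = sub[sel]
            if len(ss) == 0:
                continue
            if nsrc == 1:
                s1 = sxyz[sel][:, 0]
                o1 = sons[sel][:, 0]

                def t0_single(p, Me, s1=s1, o1=o1):
                    d = p - s1
                    return o1 + np.sqrt(np.einsum("kj,kjl,kl->k", d, Me, d))

                A, cand = minimize_on_faces(ss, t0_single)
            else:
                s4 = sxyz[sel]
                o4 = sons[sel]

                def t0_multi(p, Me, s4=s4, o4=o4):
                    d = p[:, None, :] - s4                      # (k, 4, 3)
                    dist = np.sqrt(np.einsum("kqj,kjl,kql->kq", d, Me, d))
                    return np.min(o4 + dist, axis=1)

                A, cand = minimize_on_faces(ss, t0_multi)
            np.minimum.at(new, A, cand)
        # the continuum solution can never precede the earliest onset
        np.maximum(new, floor, out=new)
        improved = np.flatnonzero(at - new > tol)
        at = new
        if len(improved) == 0:
            break
        touch = inc[improved]
        active = np.zeros(ncand, dtype=bool)
        active[np.unique(touch.indices)] = True
    return at
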