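"""Idealized biventricular anatomy generation.

Stands in for CT/MRI-derived patient geometry: a truncated two-ellipsoid
ventricle pair (thick-walled LV, thinner crescent RV) meshed with tetrahedra,
carrying the labels the downstream electrophysiology needs — wall identity
(LV free wall / septum / RV free wall), transmural layer (endo/mid/epi),
AHA 17-segment codes for the LV, tissue class (normal / fibrosis / scar),
rule-based fiber orientations and endocardial surface node sets.

Units are mm throughout; node indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree

logger = logging.getLogger(__name__)

# wall labels
WALL_LV_FREE = 0
WALL_SEPTUM = 1
WALL_RV_FREE = 2
WALL_NAMES = {WALL_LV_FREE: "LV_free", WALL_SEPTUM: "septum", WALL_RV_FREE: "RV_free"}

# transmural layers
LAYER_ENDO = 0
LAYER_MID = 1
LAYER_EPI = 2
LAYER_NAMES = {LAYER_ENDO: "endo", LAYER_MID: "mid", LAYER_EPI: "epi"}

# tissue classes
TISSUE_NORMAL = 0
TISSUE_FIBROSIS = 1
TISSUE_SCAR = 2
TISSUE_NAMES = {TISSUE_NORMAL: "normal", TISSUE_FIBROSIS: "fibrosis", TISSUE_SCAR: "scar"}

#: AHA segments conventionally assigned to the interventricular septum.
SEPTAL_SEGMENTS = frozenset({2, 3, 8, 9, 14})


@dataclass(frozen=True)
class ShapeParams:
    """Truncated-ellipsoid shape of the ventricle pair.

    The LV is a thick shell between two concentric ellipsoids centred at the
    origin; the RV is a thinner shell around an ellipsoid shifted toward +x
    (the patient's right), clipped against the LV epicardium so the shared
    wall (septum) belongs to the LV.  Everything is truncated at the base
    plane ``z = 0``; the long axis is -z (apex down).
    """

    lv_endo_radii: tuple[float, float, float] = (30.0, 30.0, 55.0)
    lv_wall: float = 9.0
    rv_center: tuple[float, float, float] = (18.0, 0.0, -4.0)
    rv_epi_radii: tuple[float, float, float] = (52.0, 34.0, 56.0)
    rv_wall: float = 5.0

    def __post_init__(self) -> None:
        if self.lv_wall <= 0 or self.rv_wall <= 0:
            raise ValueError("wall thickness must be positive")
        if min(self.lv_endo_radii) <= 0 or min(self.rv_epi_radii) <= 0:
            raise ValueError("ellipsoid radii must be positive")
        if self.rv_wall >= min(self.rv_epi_radii):
            raise ValueError("RV wall thickness must be smaller than RV radii")

    @property
    def lv_epi_radii(self) -> np.ndarray:
        return np.asarray(self.lv_endo_radii) + self.lv_wall

    @property
    def rv_endo_radii(self) -> np.ndarray:
        return np.asarray(self.rv_epi_radii) - self.rv_wall


@dataclass
class VentricularMesh:
    """Labeled tetrahedral biventricular geometry.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    tets : (M, 4) int array of node indices
    element_volume : (M,) float array, mm^3
    wall_label : (M,) int, one of ``WALL_*``
    wall_label_node : (N,) int
    layer_label : (M,) int, one of ``LAYER_*``
    aha_segment : (M,) int, 1..17 for LV elements, 0 for RV
    tissue_class : (M,) int, one of ``TISSUE_*``
    fiber : (M, 3) unit vectors
    depth : (M,) normalized transmural depth, 0 at endo and 1 at epi
    endo_surface_LV, endo_surface_RV : int arrays of node indices
    """

    nodes: np.ndarray
    tets: np.ndarray
    element_volume: np.ndarray
    wall_label: np.ndarray
    wall_label_node: np.ndarray
    layer_label: np.ndarray
    aha_segment: np.ndarray
    tissue_class: np.ndarray
    fiber: np.ndarray
    depth: np.ndarray
    endo_surface_LV: np.ndarray
    endo_surface_RV: np.ndarray
    edge_length: float
    shape: ShapeParams | None = None
    fiber_flagged: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def lv_elements(self) -> np.ndarray:
        return np.flatnonzero(self.wall_label != WALL_RV_FREE)

    def node_volume(self) -> np.ndarray:
        """Lumped nodal volumes (mm^3): each non-scar element spreads its
        volume equally over its four nodes."""
        w = np.zeros(self.n_nodes)
        keep = self.tissue_class != TISSUE_SCAR
        np.add.at(w, self.tets[keep].ravel(),
                  np.repeat(self.element_volume[keep] / 4.0, 4))
        return w

    def node_is_scar(self) -> np.ndarray:
        """True where every incident element is scar (node cannot activate)."""
        any_ok = np.zeros(self.n_nodes, dtype=bool)
        keep = self.tissue_class != TISSUE_SCAR
        any_ok[self.tets[keep].ravel()] = True
        return ~any_ok


@dataclass(frozen=True)
class TorsoModel:
    """Nine physical 12-lead electrode positions (mm), torso frame.

    +x is the patient's right, +y anterior, +z toward the head.
    """

    electrodes: dict[str, tuple[float, float, float]]

    REQUIRED = ("RA", "LA", "LL", "V1", "V2", "V3", "V4", "V5", "V6")

    def __post_init__(self) -> None:
        missing = [e for e in self.REQUIRED if e not in self.electrodes]
        if missing:
            raise ValueError(f"missing electrodes: {missing}")
        coords = np.array([self.electrodes[e] for e in self.REQUIRED])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(coords), 1)] < 1e-9):
            raise ValueError("electrode positions must be pairwise distinct")

    def coords(self) -> np.ndarray:
        return np.array([self.electrodes[e] for e in self.REQUIRED], dtype=float)


def default_torso() -> TorsoModel:
    """Fixed synthetic electrode landmarks around the heart-centred frame.

    The positions are not patient-derived; they are plausible surface
    landmarks placed well outside the ventricular bounding box.
    """
    return TorsoModel(electrodes={
        "RA": (140.0, 40.0, 220.0),
        "LA": (-140.0, 40.0, 220.0),
        "LL": (-90.0, 20.0, -420.0),
        "V1": (35.0, 120.0, 10.0),
        "V2": (-10.0, 125.0, 10.0),
        "V3": (-45.0, 118.0, -5.0),
        "V4": (-75.0, 102.0, -20.0),
        "V5": (-100.0, 78.0, -20.0),
        "V6": (-118.0, 48.0, -20.0),
    })


@dataclass(frozen=True)
class LesionSpec:
    """Schematic 17-segment x 3-layer map of myocardial damage.

    ``entries`` maps ``(segment, layer)`` to ``"fibrosis"`` or ``"scar"``;
    layers may be given as names ('endo'/'mid'/'epi') or codes 0..2.
    """

    entries: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[tuple[int, int], str] = {}
        layer_by_name = {v: k for k, v in LAYER_NAMES.items()}
        for (seg, layer), cls in self.entries.items():
            if isinstance(layer, str):
                if layer not in layer_by_name:
                    raise ValueError(f"unknown layer {layer!r}")
                layer = layer_by_name[layer]
            if not (1 <= int(seg) <= 17):
                raise ValueError(
                    f"lesion map is LV-only: segment {seg} outside 1..17")
            if layer not in (0, 1, 2):
                raise ValueError(f"layer {layer} outside 0..2")
            if cls not in ("fibrosis", "scar"):
                raise ValueError(f"unknown tissue class {cls!r}")
            norm[(int(seg), int(layer))] = cls
        object.__setattr__(self, "entries", norm)


@dataclass
class PacingConfig:
    """Pacing protocol: intrinsic LBBB or biventricular stimulation."""

    mode: str  # 'lbbb' or 'biv'
    rv_site: int | None = None
    lv_site: int | None = None
    rv_lv_delay: float = 0.0  # ms; zero per protocol

    def __post_init__(self) -> None:
        if self.mode not in ("lbbb", "biv"):
            raise ValueError("mode must be 'lbbb' or 'biv'")
        if self.mode == "biv" and (self.rv_site is None or self.lv_site is None):
            raise ValueError("BiV pacing requires both RV and LV sites")


# ---------------------------------------------------------------------------
# geometry predicates
# ---------------------------------------------------------------------------

def _quad(pts: np.ndarray, center, radii) -> np.ndarray:
    """sum(((p - c) / r)^2); <1 inside the ellipsoid."""
    d = (np.atleast_2d(pts) - np.asarray(center)) / np.asarray(radii, dtype=float)
    return np.einsum("ij,ij->i", d, d)


def _region_masks(shape: ShapeParams, pts: np.ndarray, tol: float = 0.0):
    pts = np.atleast_2d(pts)
    z_ok = pts[:, 2] <= tol
    g_lv_endo = _quad(pts, (0, 0, 0), shape.lv_endo_radii)
    g_lv_epi = _quad(pts, (0, 0, 0), shape.lv_epi_radii)
    g_rv_endo = _quad(pts, shape.rv_center, shape.rv_endo_radii)
    g_rv_epi = _quad(pts, shape.rv_center, shape.rv_epi_radii)
    lv_shell = z_ok & (g_lv_epi <= 1 + tol) & (g_lv_endo >= 1 - tol)
    rv_shell = (z_ok & (g_rv_epi <= 1 + tol) & (g_rv_endo >= 1 - tol)
                & (g_lv_epi >= 1 - tol))
    lv_cavity = z_ok & (g_lv_endo < 1)
    rv_cavity = z_ok & (g_rv_endo < 1) & (g_lv_epi > 1)
    return lv_shell, rv_shell, lv_cavity, rv_cavity


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1 + 5 ** 0.5) / 2
    z = 1 - 2 * (i + 0.5) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _ellipsoid_area(radii) -> float:
    # Knud Thomsen approximation, p = 1.6075
    a, b, c = np.asarray(radii, dtype=float)
    p = 1.6075
    return 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)


def _surface_points(center, radii, h: float) -> np.ndarray:
    n = max(64, int(np.ceil(1.2 * _ellipsoid_area(radii) / h ** 2)))
    dirs = _fibonacci_sphere(n)
    return np.asarray(center) + dirs * np.asarray(radii, dtype=float)


def _tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0


def _solve_depth(pts: np.ndarray, center, radii_in, wall: float,
                 n_iter: int = 48) -> np.ndarray:
    """Normalized transmural depth by bisection on the interpolated ellipsoid
    family r(s) = r_in + s * wall (s = 0 at endo, 1 at epi)."""
    pts = np.atleast_2d(pts)
    lo = np.zeros(len(pts))
    hi = np.ones(len(pts))
    r_in = np.asarray(radii_in, dtype=float)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        r = r_in + mid[:, None] * wall
        d = (pts - np.asarray(center)) / r
        g = np.einsum("ij,ij->i", d, d)
        outside = g > 1.0
        lo = np.where(outside, mid, lo)
        hi = np.where(outside, hi, mid)
    return 0.5 * (lo + hi)


def aha_sector(theta_deg: np.ndarray, level: np.ndarray) -> np.ndarray:
    """AHA segment from circumferential angle and long-axis level.

    ``theta_deg`` is measured from +x (toward the RV, i.e. the septum) in the
    short-axis plane; ``level`` is 0 basal, 1 mid, 2 apical, 3 apex.
    Basal and mid sectors subtend 60 degrees, apical sectors 90 degrees.
    """
    theta = np.mod(np.asarray(theta_deg, dtype=float) + 180.0, 360.0) - 180.0
    level = np.asarray(level)
    seg = np.zeros(theta.shape, dtype=np.int32)

    # 60-degree sectors, ordered so the two septal segments face +x.
    basal = np.select(
        [(theta >= 0) & (theta < 60), (theta >= 60) & (theta < 120),
         (theta >= 120), (theta < -120),
         (theta >= -120) & (theta < -60), (theta >= -60) & (theta < 0)],
        [2, 1, 6, 5, 4, 3])
    mid = np.select(
        [(theta >= 0) & (theta < 60), (theta >= 60) & (theta < 120),
         (theta >= 120), (theta < -120),
         (theta >= -120) & (theta < -60), (theta >= -60) & (theta < 0)],
        [8, 7, 12, 11, 10, 9])
    apical = np.select(
        [(theta >= -45) & (theta < 45), (theta >= 45) & (theta < 135),
         (theta >= 135) | (theta < -135), (theta >= -135) & (theta < -45)],
        [14, 13, 16, 15])
    seg = np.select([level == 0, level == 1, level == 2, level == 3],
                    [basal, mid, apical, np.full_like(basal, 17)])
    return seg


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def build_ventricles(shape: ShapeParams | None = None,
                     edge_length: float = 4.0,
                     seed: int = 0) -> VentricularMesh:
    """Generate a labeled truncated two-ellipsoid biventricular mesh.

    Interior nodes come from a regular grid at ``edge_length`` spacing;
    boundary surfaces (LV/RV endo and epi, base plane) are sampled at the
    same density so the mesh volume tracks the analytic shell volume.
    Deterministic for a fixed seed.
    """
    if shape is None:
        shape = ShapeParams()
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    h = float(edge_length)
    del seed  # construction is fully deterministic; seed kept for API stability

    lv_epi = shape.lv_epi_radii
    rv_c = np.asarray(shape.rv_center)
    rv_epi = np.asarray(shape.rv_epi_radii, dtype=float)
    lo = np.minimum(-lv_epi, rv_c - rv_epi) - h
    hi = np.maximum(lv_epi, rv_c + rv_epi) + h
    hi[2] = 0.0
    axes = [np.arange(lo[k], hi[k] + 0.5 * h, h) for k in range(2)]
    z_axis = -np.arange(0.0, -lo[2] + 0.5 * h, h)[::-1]
    gx, gy, gz = np.meshgrid(axes[0], axes[1], z_axis, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    lv_s, rv_s, _, _ = _region_masks(shape, grid)
    pts = [grid[lv_s | rv_s]]

    surf = []
    s = _surface_points((0, 0, 0), shape.lv_endo_radii, h)
    surf.append(s[s[:, 2] <= 0])
    s = _surface_points((0, 0, 0), lv_epi, h)
    surf.append(s[s[:, 2] <= 0])
    for radii in (shape.rv_endo_radii, rv_epi):
        s = _surface_points(rv_c, radii, h)
        keep = (s[:, 2] <= 0) & (_quad(s, (0, 0, 0), lv_epi) > 1)
        surf.append(s[keep])
    pts.append(np.concatenate(surf))
    points = np.concatenate(pts)
    points = points[np.lexsort(points.T)]
    # drop near-duplicates that would create degenerate tets
    keep = np.ones(len(points), dtype=bool)
    tree = cKDTree(points)
    pairs = tree.query_pairs(0.25 * h, output_type="ndarray")
    keep[pairs[:, 1]] = False
    points = points[keep]

    tri = Delaunay(points, qhull_options="QJ Pp")
    tets = tri.simplices
    vols = _tet_volumes(points, tets)
    cent = points[tets].mean(axis=1)
    lv_s, rv_s, _, _ = _region_masks(shape, cent)
    keep = (vols > 1e-9) & (lv_s | rv_s)
    tets, vols, cent = tets[keep], vols[keep], cent[keep]
    lv_s, rv_s = lv_s[keep], rv_s[keep]

    # keep the largest node-connected component of elements
    m = len(tets)
    elem_ids = np.repeat(np.arange(m), 4)
    inc = coo_matrix((np.ones(4 * m), (elem_ids, tets.ravel())),
                     shape=(m, len(points))).tocsr()
    adj = inc @ inc.T
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        main = np.argmax(np.bincount(labels))
        sel = labels == main
        tets, vols, cent, lv_s, rv_s = (tets[sel], vols[sel], cent[sel],
                                        lv_s[sel], rv_s[sel])

    # reindex nodes
    used = np.unique(tets)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    tets = remap[tets]

    # element classification
    m = len(tets)
    is_lv = lv_s  # LV has priority over RV where shells touch
    is_rv = rv_s & ~lv_s
    depth = np.zeros(m)
    depth[is_lv] = _solve_depth(cent[is_lv], (0, 0, 0),
                                shape.lv_endo_radii, shape.lv_wall)
    if np.any(is_rv):
        depth[is_rv] = _solve_depth(cent[is_rv], rv_c,
                                    shape.rv_endo_radii, shape.rv_wall)
    layer = np.minimum((depth * 3).astype(np.int32), 2)

    aha = np.zeros(m, dtype=np.int32)
    c_endo = shape.lv_endo_radii[2]
    zf = -cent[:, 2] / c_endo
    level = np.minimum((zf * 3).astype(np.int32), 2)
    level[zf >= 1.0] = 3
    theta = np.degrees(np.arctan2(cent[:, 1], cent[:, 0]))
    aha[is_lv] = aha_sector(theta[is_lv], level[is_lv])

    wall = np.full(m, WALL_RV_FREE, dtype=np.int32)
    wall[is_lv] = np.where(np.isin(aha[is_lv], list(SEPTAL_SEGMENTS)),
                           WALL_SEPTUM, WALL_LV_FREE)

    # node wall labels by incident-element majority
    counts = np.zeros((len(nodes), 3), dtype=np.int32)
    for lab in (WALL_LV_FREE, WALL_SEPTUM, WALL_RV_FREE):
        sel = wall == lab
        np.add.at(counts[:, lab], tets[sel].ravel(), 1)
    wall_node = np.argmax(counts, axis=1).astype(np.int32)

    endo_lv, endo_rv = _endocardial_surfaces(shape, nodes, tets, h)

    mesh = VentricularMesh(
        nodes=nodes, tets=tets, element_volume=vols,
        wall_label=wall, wall_label_node=wall_node,
        layer_label=layer, aha_segment=aha,
        tissue_class=np.zeros(m, dtype=np.int32),
        fiber=np.zeros((m, 3)), depth=depth,
        endo_surface_LV=endo_lv, endo_surface_RV=endo_rv,
        edge_length=h, shape=shape,
    )
    assign_fibers(mesh)
    return mesh


def _endocardial_surfaces(shape: ShapeParams, nodes: np.ndarray,
                          tets: np.ndarray, h: float):
    """Boundary faces whose outward side lies in a cavity define the
    endocardial node sets.  The RV endocardium includes the septal face
    (geometrically the LV epicardial surface bounding the RV cavity)."""
    faces = np.concatenate([tets[:, [0, 1, 2]], tets[:, [0, 1, 3]],
                            tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]])
    owner = np.tile(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T)
    key_s, faces_s, owner_s = key[order], faces[order], owner[order]
    new = np.ones(len(key_s), dtype=bool)
    new[1:] = np.any(key_s[1:] != key_s[:-1], axis=1)
    grp = np.cumsum(new) - 1
    cnt = np.bincount(grp)
    boundary = cnt[grp] == 1
    bfaces, bowner = faces_s[boundary], owner_s[boundary]

    fc = nodes[bfaces].mean(axis=1)
    n = np.cross(nodes[bfaces[:, 1]] - nodes[bfaces[:, 0]],
                 nodes[bfaces[:, 2]] - nodes[bfaces[:, 0]])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    tc = nodes[tets[bowner]].mean(axis=1)
    flip = np.einsum("ij,ij->i", n, fc - tc) < 0
    n[flip] *= -1
    probe = fc + 0.3 * h * n
    _, _, lv_cav, rv_cav = _region_masks(shape, probe)
    endo_lv = np.unique(bfaces[lv_cav])
    endo_rv = np.unique(bfaces[rv_cav])
    return endo_lv, endo_rv


def assign_fibers(mesh: VentricularMesh, alpha_endo: float = 60.0,
                  alpha_epi: float = -60.0) -> VentricularMesh:
    """Rule-based fibers: helix angle interpolates linearly from
    ``alpha_endo`` (endocardium) to ``alpha_epi`` (epicardium) across the
    transmural depth; vectors are tangent to the interpolated wall surface.

    Elements where the longitudinal direction is undefined (apex cap, wall
    normal parallel to the long axis) are flagged and given a circumferential
    fiber.  Modifies ``mesh`` in place and returns it.
    """
    if mesh.shape is None:
        raise ValueError("mesh has no analytic shape; cannot assign fibers")
    shape = mesh.shape
    cent = mesh.element_centroids()
    is_rv = mesh.wall_label == WALL_RV_FREE
    center = np.where(is_rv[:, None], np.asarray(shape.rv_center), 0.0)
    r_in = np.where(is_rv[:, None], shape.rv_endo_radii,
                    np.asarray(shape.lv_endo_radii, dtype=float))
    wall_t = np.where(is_rv, shape.rv_wall, shape.lv_wall)
    radii = r_in + mesh.depth[:, None] * wall_t[:, None]

    n = (cent - center) / radii ** 2
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    zhat = np.array([0.0, 0.0, 1.0])
    t = zhat - n * n[:, 2:3]
    tn = np.linalg.norm(t, axis=1)
    flagged = tn < 1e-6
    t[flagged] = 0.0
    e_long = np.divide(t, np.maximum(tn, 1e-30)[:, None])
    e_circ = np.cross(n, e_long)
    if np.any(flagged):
        # circumferential fallback: any tangent direction
        aux = np.tile(np.array([1.0, 0.0, 0.0]), (flagged.sum(), 1))
        ec = np.cross(n[flagged], aux)
        ec /= np.linalg.norm(ec, axis=1, keepdims=True)
        e_circ[flagged] = ec
        e_long[flagged] = 0.0

    alpha = np.radians(alpha_endo + mesh.depth * (alpha_epi - alpha_endo))
    alpha[flagged] = 0.0
    fiber = np.cos(alpha)[:, None] * e_circ + np.sin(alpha)[:, None] * e_long
    fiber /= np.linalg.norm(fiber, axis=1, keepdims=True)
    mesh.fiber = fiber
    mesh.fiber_flagged = flagged
    return mesh


def transmural_normals(mesh: VentricularMesh) -> np.ndarray:
    """Outward transmural unit normals from the ellipsoid parameterization."""
    if mesh.shape is None:
        raise ValueError("mesh has no analytic shape")
    shape = mesh.shape
    cent = mesh.element_centroids()
    is_rv = mesh.wall_label == WALL_RV_FREE
    center = np.where(is_rv[:, None], np.asarray(shape.rv_center), 0.0)
    r_in = np.where(is_rv[:, None], shape.rv_endo_radii,
                    np.asarray(shape.lv_endo_radii, dtype=float))
    wall_t = np.where(is_rv, shape.rv_wall, shape.lv_wall)
    radii = r_in + mesh.depth[:, None] * wall_t[:, None]
    n = (cent - center) / radii ** 2
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def apply_lesions(mesh: VentricularMesh, spec: LesionSpec) -> VentricularMesh:
    """Assign tissue classes from the (segment, layer) damage map.

    Scar is later treated as inexcitable, fibrosis as 1% conductivity.
    Modifies ``mesh`` in place and returns it.
    """
    tissue = np.zeros(mesh.n_elements, dtype=np.int32)
    cls_code = {"fibrosis": TISSUE_FIBROSIS, "scar": TISSUE_SCAR}
    for (seg, layer), cls in spec.entries.items():
        sel = ((mesh.aha_segment == seg) & (mesh.layer_label == layer)
               & (mesh.wall_label != WALL_RV_FREE))
        tissue[sel] = cls_code[cls]
    mesh.tissue_class = tissue
    n_fib = int(np.sum(tissue == TISSUE_FIBROSIS))
    n_scar = int(np.sum(tissue == TISSUE_SCAR))
    logger.info("lesion map applied: %d fibrosis, %d scar elements",
                n_fib, n_scar)
    return mesh


_LV_SITE_PRESETS = {"posterolateral": -150.0, "lateral": 180.0,
                    "anterolateral": 150.0}


def place_pacing_sites(mesh: VentricularMesh, rv_rule: str = "apex",
                       lv_rule: str = "posterolateral",
                       seed: int = 0) -> PacingConfig:
    """RV lead at the RV endocardial apex; LV lead on the epicardial
    lateral-wall band reachable through the coronary sinus.

    If the requested LV position lands on scar, the nearest non-scar
    candidate substitutes (with a warning).  Deterministic per seed.
    """
    if rv_rule != "apex":
        raise ValueError("only the apex rule is supported for the RV site")
    if lv_rule not in _LV_SITE_PRESETS:
        raise ValueError(f"unknown lv_rule {lv_rule!r}")
    scar_node = mesh.node_is_scar()

    rv_nodes = mesh.endo_surface_RV
    rv_ok = rv_nodes[~scar_node[rv_nodes]]
    rv_site = int(rv_ok[np.argmin(mesh.nodes[rv_ok, 2])])

    # LV epicardial candidates: boundary of LV elements at epi layer
    lv_epi_elems = np.flatnonzero((mesh.wall_label != WALL_RV_FREE)
                                  & (mesh.layer_label == LAYER_EPI))
    cand = np.unique(mesh.tets[lv_epi_elems])
    endo = set(mesh.endo_surface_LV.tolist()) | set(mesh.endo_surface_RV.tolist())
    cand = np.array([c for c in cand if c not in endo], dtype=np.int64)
    p = mesh.nodes[cand]
    theta = np.degrees(np.arctan2(p[:, 1], p[:, 0]))
    theta0 = _LV_SITE_PRESETS[lv_rule]
    dtheta = np.mod(theta - theta0 + 180.0, 360.0) - 180.0
    z_ref = (-0.5 * mesh.shape.lv_endo_radii[2]) if mesh.shape else p[:, 2].mean()
    r_mean = float(np.linalg.norm(p[:, :2], axis=1).mean())
    cost = (np.radians(dtheta) * r_mean) ** 2 + (p[:, 2] - z_ref) ** 2
    order = np.argsort(cost)
    lv_site = int(cand[order[0]])
    if scar_node[lv_site]:
        for idx in order[1:]:
            if not scar_node[cand[idx]]:
                logger.warning("requested LV site on scar; nearest non-scar "
                               "candidate substituted")
                lv_site = int(cand[idx])
                break
        else:
            raise ValueError("no non-scar LV epicardial candidate found")
    del seed  # site rules are deterministic; seed kept for API stability
    return PacingConfig(mode="biv", rv_site=rv_site, lv_site=lv_site,
                        rv_lv_delay=0.0)


# ---------------------------------------------------------------------------
# structured slab (validation geometry)
# ---------------------------------------------------------------------------

def build_slab(size=(80.0, 40.0, 10.0), edge_length: float = 2.0,
               fiber_dir=(1.0, 0.0, 0.0)) -> VentricularMesh:
    """Rectangular slab with uniform fibers, meshed by a Kuhn (6-tet)
    subdivision of a regular cube lattice.  Used for front-speed and
    convergence validation; labels are filled with placeholders."""
    h = float(edge_length)
    nx, ny, nz = (int(round(s / h)) for s in size)
    xs = np.arange(nx + 1) * h
    ys = np.arange(ny + 1) * h
    zs = np.arange(nz + 1) * h
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    v = {(a, b, c): nid(i + a, j + b, k + c)
         for a in (0, 1) for b in (0, 1) for c in (0, 1)}
    kuhn = [((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
            ((0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)),
            ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)),
            ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
            ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
            ((0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1))]
    tets = np.concatenate([np.column_stack([v[a], v[b], v[c], v[d]])
                           for a, b, c, d in kuhn])
    m = len(tets)
    vols = np.full(m, h ** 3 / 6.0)
    fiber = np.tile(np.asarray(fiber_dir, dtype=float)
                    / np.linalg.norm(fiber_dir), (m, 1))
    return VentricularMesh(
        nodes=nodes, tets=tets, element_volume=vols,
        wall_label=np.zeros(m, dtype=np.int32),
        wall_label_node=np.zeros(len(nodes), dtype=np.int32),
        layer_label=np.full(m, LAYER_MID, dtype=np.int32),
        aha_segment=np.ones(m, dtype=np.int32),
        tissue_class=np.zeros(m, dtype=np.int32),
        fiber=fiber, depth=np.full(m, 0.5),
        endo_surface_LV=np.array([], dtype=np.int64),
        endo_surface_RV=np.array([], dtype=np.int64),
        edge_length=h, shape=None,
    )


def analytic_shell_volume(shape: ShapeParams, n_samples: int = 400_000,
                          seed: int = 12345) -> float:
    """Monte-Carlo reference for the myocardial volume (mm^3) of the
    truncated two-ellipsoid shell, accurate to ~0.5% at default sampling."""
    rng = np.random.default_rng(seed)
    lv_epi = shape.lv_epi_radii
    rv_c = np.asarray(shape.rv_center)
    rv_epi = np.asarray(shape.rv_epi_radii, dtype=float)
    lo = np.minimum(-lv_epi, rv_c - rv_epi)
    hi = np.maximum(lv_epi, rv_c + rv_epi)
    hi = hi.copy()
    hi[2] = 0.0
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    lv_s, rv_s, _, _ = _region_masks(shape, pts)
    frac = np.mean(lv_s | rv_s)
    return float(frac * np.prod(hi - lo))
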