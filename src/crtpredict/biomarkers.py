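"""Model-derived biomarkers of ventricular activation and geometry.

Per pacing mode (LBBB baseline, BiV pacing):

* TAT      — total activation time, AT_max - AT_min (ms);
* QRSd     — maximum per-lead QRS duration (ms), from the forward ECG;
* AT_RVLV  — interventricular dyssynchrony: latest LV activation minus
             latest RV activation (ms, positive = LV later);
* mAT_STLV — intraventricular dyssynchrony: (mean AT of the LV free wall -
             mean AT of the septum) / TAT (dimensionless);
* IntAV_STLV — integral over time of |activated volume fraction of the LV
             free wall - activated volume fraction of the septum| (ms).

Geometry features from the labeled anatomy: myocardial tissue volume MTV
(ml, scar excluded — scar neither excites nor contracts), lesion volume
InfarctV (ml) and its ratio to MTV, and ruler-like geodesic distances from
the LV pacing site to the RV pacing site (DLvRv), to the lesion border
(DLvInfarct) and to the late-activation zone (DLvLATZ), all in mm.

Pacing-induced changes are expressed relative to the LBBB baseline,
dX = (X_BiV - X_LBBB) / X_LBBB, except for the already-normalized mAT_STLV
whose change is reported as an absolute increment.  Undefined quantities
(no lesion, zero TAT, zero baseline) carry NaN missing-value markers — not
zeros — so downstream missing-feature handling is exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .anatomy import (TISSUE_NORMAL, TISSUE_SCAR, WALL_LV_FREE,
                      WALL_RV_FREE, WALL_SEPTUM, PacingConfig,
                      VentricularMesh)
from .eikonal import ActivationMap, geodesic_field

logger = logging.getLogger(__name__)

#: features whose pacing-induced change is an absolute increment, not a ratio
ABSOLUTE_DELTA_FEATURES = ("mAT_STLV",)


@dataclass
class ActivationVolumeCurves:
    t: np.ndarray
    av_st: np.ndarray       # activated septal volume at t, mm^3
    av_lat: np.ndarray      # activated LV-free-wall volume at t, mm^3
    v_st: float             # total septal volume, mm^3 (scar excluded)
    v_lat: float            # total LV-free-wall volume, mm^3


def tat(amap: ActivationMap) -> float:
    """Total activation time AT_max - AT_min over finite nodes (ms)."""
    if not np.any(amap.finite):
        raise ValueError("activation map has no finite nodes")
    return amap.at_max - amap.at_min


def at_rvlv(amap: ActivationMap, mesh: VentricularMesh) -> float:
    """Latest LV activation minus latest RV activation (ms).

    The LV here includes the septum, which activates with the left chamber
    in the left-bundle-branch-block pattern.
    """
    lv = np.isin(mesh.wall_label_node, (WALL_LV_FREE, WALL_SEPTUM))
    rv = mesh.wall_label_node == WALL_RV_FREE
    lv_at = amap.at[lv & amap.finite]
    rv_at = amap.at[rv & amap.finite]
    if lv_at.size == 0 or rv_at.size == 0:
        raise ValueError("a chamber has no finite activation times")
    return float(lv_at.max() - rv_at.max())


def mat_stlv(amap: ActivationMap, mesh: VentricularMesh,
             volume_weighted: bool = True) -> float:
    """(mean LV-free-wall AT - mean septal AT) / TAT; NaN when TAT = 0.

    Node means are weighted by lumped nodal volumes by default.
    """
    span = tat(amap)
    if span <= 0:
        return float("nan")
    w = mesh.node_volume() if volume_weighted else np.ones(mesh.n_nodes)
    out = []
    for label in (WALL_LV_FREE, WALL_SEPTUM):
        sel = (mesh.wall_label_node == label) & amap.finite & (w > 0)
        if not np.any(sel):
            raise ValueError("region has no finite activation times")
        out.append(np.average(amap.at[sel], weights=w[sel]))
    return float((out[0] - out[1]) / span)


def activation_volume_curves(amap: ActivationMap, mesh: VentricularMesh,
                             dt: float = 1.0) -> ActivationVolumeCurves:
    """Cumulative activated-volume curves for septum and LV free wall.

    An element counts as activated once its mean nodal activation time has
    passed; scar is excluded from both the numerators and the totals.
    """
    at_e = amap.at[mesh.tets].mean(axis=1)
    ok = np.isfinite(at_e) & (mesh.tissue_class != TISSUE_SCAR)
    t0, t1 = amap.at_min, amap.at_max
    t = np.arange(t0, t1 + dt / 2, dt)
    if t.size == 0 or t[-1] < t1:
        t = np.append(t, t1)
    curves = {}
    totals = {}
    for key, label in (("st", WALL_SEPTUM), ("lat", WALL_LV_FREE)):
        sel = ok & (mesh.wall_label == label)
        vols = mesh.element_volume[sel]
        times = at_e[sel]
        order = np.argsort(times)
        csum = np.concatenate([[0.0], np.cumsum(vols[order])])
        idx = np.searchsorted(times[order], t, side="right")
        curves[key] = csum[idx]
        totals[key] = float(vols.sum())
    return ActivationVolumeCurves(t=t, av_st=curves["st"], av_lat=curves["lat"],
                                  v_st=totals["st"], v_lat=totals["lat"])


def integral_abs_fraction_difference(t: np.ndarray, f1: np.ndarray,
                                     f2: np.ndarray) -> float:
    """Trapezoidal integral of |f1 - f2| over t (ms for fraction curves)."""
    return float(np.trapezoid(np.abs(np.asarray(f1) - np.asarray(f2)), t))


def intav_stlv(amap: ActivationMap, mesh: VentricularMesh,
               dt: float = 1.0) -> float:
    """Integral index of LV dyssynchrony (ms): area between the septal and
    LV-free-wall activated-volume fraction curves."""
    c = activation_volume_curves(amap, mesh, dt=dt)
    if c.v_st <= 0 or c.v_lat <= 0:
        raise ValueError("empty septal or LV free-wall region")
    return integral_abs_fraction_difference(c.t, c.av_st / c.v_st,
                                            c.av_lat / c.v_lat)


def geometry_features(mesh: VentricularMesh, pacing: PacingConfig,
                      lat_zone: np.ndarray | None = None) -> dict[str, float]:
    """MTV, lesion volume and pacing-site distance features.

    Distances are isotropic unit-speed geodesics (ruler-like; scar stays in
    the domain).  ``DLvInfarct`` is NaN when the anatomy carries no lesion,
    ``DLvLATZ`` NaN when no late-activation zone is supplied.
    """
    if pacing.lv_site is None or pacing.rv_site is None:
        raise ValueError("geometry features need both pacing sites")
    vols = mesh.element_volume
    mtv = float(vols[mesh.tissue_class != TISSUE_SCAR].sum()) / 1000.0  # ml
    lesion = mesh.tissue_class != TISSUE_NORMAL
    infarct_v = float(vols[lesion].sum()) / 1000.0
    field = geodesic_field(mesh, pacing.lv_site)
    out = {
        "MTV": mtv,
        "InfarctV": infarct_v,
        "InfarctV_MTV": infarct_v / mtv if mtv > 0 else float("nan"),
        "DLvRv": float(field[pacing.rv_site]),
    }
    if np.any(lesion):
        lesion_nodes = np.unique(mesh.tets[lesion])
        out["DLvInfarct"] = float(field[lesion_nodes].min())
    else:
        out["DLvInfarct"] = float("nan")
    if lat_zone is not None and len(lat_zone):
        out["DLvLATZ"] = float(field[np.asarray(lat_zone, dtype=int)].min())
    else:
        out["DLvLATZ"] = float("nan")
    return out


def activation_biomarkers(amap: ActivationMap, mesh: VentricularMesh,
                          qrsd: float | None = None,
                          mtv_ml: float | None = None,
                          dt: float = 1.0) -> dict[str, float]:
    """The per-mode activation indices as a flat dict."""
    if mtv_ml is None:
        mtv_ml = float(
            mesh.element_volume[mesh.tissue_class != TISSUE_SCAR].sum()) / 1000.0
    span = tat(amap)
    out = {
        "TAT": span,
        "AT_RVLV": at_rvlv(amap, mesh),
        "mAT_STLV": mat_stlv(amap, mesh),
        "IntAV_STLV": intav_stlv(amap, mesh, dt=dt),
        "TAT_MTV": span / mtv_ml if mtv_ml > 0 else float("nan"),
    }
    if qrsd is not None:
        out["QRSd"] = float(qrsd)
    return out


def delta_features(lbbb: dict[str, float], biv: dict[str, float],
                   ) -> dict[str, float]:
    """Pacing-induced changes against the LBBB baseline.

    Relative units dX = (X_BiV - X_LBBB)/X_LBBB for every shared feature
    except the already-dimensionless mAT_STLV, which uses the absolute
    increment.  A zero baseline for a relative change yields NaN.
    """
    out = {}
    for name in lbbb:
        if name not in biv:
            continue
        x0, x1 = lbbb[name], biv[name]
        if name in ABSOLUTE_DELTA_FEATURES:
            out[f"d{name}"] = x1 - x0
        elif x0 == 0 or not np.isfinite(x0) or not np.isfinite(x1):
            out[f"d{name}"] = float("nan")
        else:
            out[f"d{name}"] = (x1 - x0) / x0
    return out
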