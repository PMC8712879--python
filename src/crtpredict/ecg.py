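"""Forward 12-lead QRS from an activation map.

Each mesh element carries a template action-potential upstroke shifted to
its activation time; the element's equivalent current dipole is

    p(t) = -A'(t - AT) * grad(AT) * volume,

where grad(AT) is the activation-time gradient over the element (linear
shape functions).  Electrode potentials follow from the
infinite-homogeneous-medium dipole kernel p . (r - x) / (4 pi |r - x|^3);
the torso and lungs are not modelled as conductivity inhomogeneities, which
preserves QRS timing and normalized morphology (the quantities the pipeline
consumes) at a fraction of the cost of a full volume-conductor solve.

Lead derivation follows the standard Wilson/Goldberger algebra, so the
Einthoven identity I + III = II and the augmented-lead identity
aVR + aVL + aVF = 0 hold to rounding.  QRS duration is measured per lead by
an amplitude-threshold rule with sub-sample interpolation; the reported QRSd
is the maximum per-lead duration across the 12 leads (the mean over leads is
also returned and is what conductivity personalization fits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .anatomy import TISSUE_SCAR, TorsoModel, VentricularMesh
from .eikonal import ActivationMap

logger = logging.getLogger(__name__)

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class APTemplate:
    """Template transmembrane upstroke (depolarization only).

    A logistic rise from rest to plateau with time constant ``tau`` ms; no
    repolarization phase is simulated because only the QRS is analysed.
    """

    rest: float = -85.0   # mV
    peak: float = 25.0    # mV
    tau: float = 0.4      # ms upstroke time constant

    def value(self, s: np.ndarray) -> np.ndarray:
        return self.rest + (self.peak - self.rest) / (1.0 + np.exp(-s / self.tau))

    def derivative(self, s: np.ndarray) -> np.ndarray:
        # the upstroke derivative is numerically zero outside ~40 tau;
        # computing the logistic only there avoids overflow and wasted exps
        z = np.asarray(s, dtype=float) / self.tau
        out = np.zeros_like(z)
        sel = np.abs(z) < 40.0
        sig = 1.0 / (1.0 + np.exp(-z[sel]))
        out[sel] = (self.peak - self.rest) / self.tau * sig * (1.0 - sig)
        return out


@dataclass
class ElectrodePotentials:
    """Raw electrode potential time series (arbitrary linear units)."""

    t: np.ndarray
    data: np.ndarray               # (9, T) rows in TorsoModel.REQUIRED order
    names: tuple[str, ...] = TorsoModel.REQUIRED
    n_skipped_elements: int = 0


@dataclass
class ECG12:
    """Sampled 12-lead QRS complexes."""

    t: np.ndarray
    signals: np.ndarray            # (12, T) in LEAD_NAMES order, mV-scaled
    dt: float
    normalized: bool = False

    def lead(self, name: str) -> np.ndarray:
        return self.signals[LEAD_NAMES.index(name)]

    def normalize(self) -> "ECG12":
        """Scale each lead by the global maximum absolute amplitude."""
        m = np.max(np.abs(self.signals))
        sig = self.signals / m if m > 0 else self.signals.copy()
        return ECG12(t=self.t.copy(), signals=sig, dt=self.dt, normalized=True)


@dataclass
class QRSMeasurement:
    onset: np.ndarray              # (12,) ms, NaN where lead silent
    offset: np.ndarray             # (12,)
    duration: np.ndarray           # (12,) ms, 0 where lead silent
    qrsd: float                    # max over leads
    mean_qrsd: float               # mean over non-silent leads
    excluded: list[str] = field(default_factory=list)


class ECGForward:
    """Cached dipole projection operator for one mesh/torso pair.

    Precomputes the element geometry and electrode kernels once so that
    repeated evaluations (the conductivity-personalization loop) only pay
    for the activation-dependent part.
    """

    def __init__(self, mesh: VentricularMesh, torso: TorsoModel,
                 ap: APTemplate | None = None, dt: float = 0.5,
                 pad: tuple[float, float] = (5.0, 10.0)) -> None:
        self.mesh = mesh
        self.ap = ap if ap is not None else APTemplate()
        self.dt = float(dt)
        self.pad = pad
        elec = torso.coords()
        tree = cKDTree(mesh.nodes)
        d_min, _ = tree.query(elec)
        if np.any(d_min < mesh.edge_length):
            raise ValueError("electrode lies inside (or on) the myocardium")
        keep = mesh.tissue_class != TISSUE_SCAR
        self.tets = mesh.tets[keep]
        self.vols = mesh.element_volume[keep]
        p0 = mesh.nodes[self.tets[:, 0]]
        self.E = mesh.nodes[self.tets[:, 1:]] - p0[:, None, :]   # (m, 3, 3)
        det = np.linalg.det(self.E)
        self.nondegenerate = np.abs(det) > 1e-12
        cent = mesh.nodes[self.tets].mean(axis=1)
        r = elec[:, None, :] - cent[None, :, :]                  # (9, m, 3)
        r3 = np.linalg.norm(r, axis=2) ** 3
        self.kern = r / (4.0 * np.pi * r3[:, :, None])

    def potentials(self, amap: ActivationMap) -> ElectrodePotentials:
        at = amap.at
        finite = np.all(np.isfinite(at[self.tets]), axis=1)
        good = finite & self.nondegenerate
        n_skip = int(np.sum(~good))
        tets = self.tets[good]
        b = at[tets[:, 1:]] - at[tets[:, 0]][:, None]
        grad = np.linalg.solve(self.E[good], b[:, :, None])[:, :, 0]
        # moment direction is -grad(AT) * volume; A' supplies the time course
        a = -np.einsum("emj,mj->em", self.kern[:, good],
                       grad * self.vols[good][:, None])          # (9, m)
        at_e = at[tets].mean(axis=1)
        t0 = float(np.min(at_e)) - self.pad[0]
        t1 = float(np.max(at_e)) + self.pad[1]
        t = np.arange(t0, t1 + self.dt / 2, self.dt)
        w = self.ap.derivative(t[None, :] - at_e[:, None])       # (m, T)
        data = a @ w
        if n_skip:
            logger.info("%d element(s) skipped in dipole sum", n_skip)
        return ElectrodePotentials(t=t, data=data, n_skipped_elements=n_skip)

    def ecg(self, amap: ActivationMap) -> ECG12:
        return derive_leads(self.potentials(amap))


def surface_potentials(amap: ActivationMap, mesh: VentricularMesh,
                       torso: TorsoModel, ap: APTemplate | None = None,
                       dt: float = 0.5, pad: tuple[float, float] = (5.0, 10.0),
                       ) -> ElectrodePotentials:
    """Project element dipoles onto the torso electrodes.

    Per element, the equivalent dipole is -A'(t - AT) * grad(AT) * volume;
    the simulated window spans [AT_min - pad[0], AT_max + pad[1]] ms.
    Elements on scar, or whose activation-time gradient is undefined
    (infinite node times, degenerate geometry), are skipped and counted.
    For repeated evaluations on one anatomy use :class:`ECGForward`.
    """
    return ECGForward(mesh, torso, ap=ap, dt=dt, pad=pad).potentials(amap)


def derive_leads(ep: ElectrodePotentials) -> ECG12:
    """Standard 12-lead derivation from the 9 physical electrodes."""
    if ep.data.shape[0] != 9:
        raise ValueError("expected 9 electrode series")
    if ep.data.shape[1] != len(ep.t):
        raise ValueError("electrode series length mismatch")
    ch = {name: ep.data[i] for i, name in enumerate(ep.names)}
    ra, la, ll = ch["RA"], ch["LA"], ch["LL"]
    wct = (ra + la + ll) / 3.0
    leads = [
        la - ra,                       # I
        ll - ra,                       # II
        ll - la,                       # III
        ra - (la + ll) / 2.0,          # aVR
        la - (ra + ll) / 2.0,          # aVL
        ll - (ra + la) / 2.0,          # aVF
    ] + [ch[f"V{k}"] - wct for k in range(1, 7)]
    dt = float(ep.t[1] - ep.t[0]) if len(ep.t) > 1 else 0.0
    return ECG12(t=ep.t.copy(), signals=np.vstack(leads), dt=dt)


def measure_qrs(ecg: ECG12, threshold_frac: float = 0.05) -> QRSMeasurement:
    """Per-lead QRS boundaries by amplitude threshold.

    Onset is the first (offset the last) crossing of
    ``threshold_frac * max|signal|`` of that lead, located with linear
    interpolation between samples; silent leads get zero duration and are
    excluded from the mean with a warning.
    """
    n_leads = ecg.signals.shape[0]
    onset = np.full(n_leads, np.nan)
    offset = np.full(n_leads, np.nan)
    duration = np.zeros(n_leads)
    excluded = []
    for i in range(n_leads):
        s = np.abs(ecg.signals[i])
        m = s.max() if s.size else 0.0
        if m <= 0:
            excluded.append(LEAD_NAMES[i] if i < len(LEAD_NAMES) else str(i))
            continue
        thr = threshold_frac * m
        above = np.flatnonzero(s > thr)
        k0, k1 = above[0], above[-1]
        t = ecg.t
        if k0 > 0:
            f = (thr - s[k0 - 1]) / (s[k0] - s[k0 - 1])
            onset[i] = t[k0 - 1] + f * (t[k0] - t[k0 - 1])
        else:
            onset[i] = t[k0]
        if k1 < len(s) - 1:
            f = (thr - s[k1 + 1]) / (s[k1] - s[k1 + 1])
            offset[i] = t[k1 + 1] - f * (t[k1 + 1] - t[k1])
        else:
            offset[i] = t[k1]
        duration[i] = offset[i] - onset[i]
    if excluded:
        logger.warning("silent lead(s) excluded from mean QRSd: %s", excluded)
    active = duration > 0
    qrsd = float(duration.max()) if active.any() else 0.0
    mean_qrsd = float(duration[active].mean()) if active.any() else 0.0
    return QRSMeasurement(onset=onset, offset=offset, duration=duration,
                          qrsd=qrsd, mean_qrsd=mean_qrsd, excluded=excluded)


def simulate_ecg(amap: ActivationMap, mesh: VentricularMesh,
                 torso: TorsoModel, ap: APTemplate | None = None,
                 dt: float = 0.5) -> ECG12:
    """Convenience: activation map -> 12-lead QRS complexes."""
    return derive_leads(surface_potentials(amap, mesh, torso, ap=ap, dt=dt))
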