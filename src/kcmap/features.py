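"""Extraction of the fourteen diagnostic variables from thickness maps.

The device-style zone layout over the central 5 mm: a central 2 mm disc
(radius 1 mm), and a 2-5 mm annulus (radii 1.0-2.5 mm) split into
superior/inferior half-annuli and eight 45-degree octants labelled by
their principal semi-meridian (T, ST, S, SN, N, IN, I, IT).  All zone
statistics are area-weighted (polar cell area is proportional to radius).

Seven variables come from the pachymetry map (SN_IT, Min, Min_Med, S_I,
Y_location, Min_Max, CCT) and seven from the epithelial map (Sup, Inf_ep,
Min_ep, Max, Min_Max_ep, SD, CET).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import ThicknessMap
from .reference import FEATURE_NAMES

#: Octant label -> central semi-meridian (degrees, oriented frame:
#: 0 = temporal, 90 = superior, counterclockwise).
OCTANT_CENTERS = {
    "T": 0.0,
    "ST": 45.0,
    "S": 90.0,
    "SN": 135.0,
    "N": 180.0,
    "IN": 225.0,
    "I": 270.0,
    "IT": 315.0,
}

HALF_ZONES = ("superior", "inferior")
ZONE_NAMES = ("central",) + HALF_ZONES + tuple(OCTANT_CENTERS)


@dataclass(frozen=True)
class ZoneGeometry:
    """Zone layout radii in mm: central disc and the 2-5 mm annulus."""

    central_radius: float = 1.0
    annulus_inner: float = 1.0
    annulus_outer: float = 2.5

    def __post_init__(self):
        if not 0 < self.central_radius <= self.annulus_inner < self.annulus_outer:
            raise ValueError("require 0 < central_radius <= annulus_inner < annulus_outer")


def orient_map(tmap: ThicknessMap, side: str) -> ThicknessMap:
    """Bring a map into the common orientation (0 deg = temporal).

    Right-eye (OD) maps are already oriented; left-eye (OS) maps are
    mirrored about the vertical axis so that nasal/temporal sectors
    coincide across eyes.
    """
    if side == "OD":
        return tmap
    if side == "OS":
        return tmap.mirrored()
    raise ValueError(f"unknown eye side {side!r}; expected 'OD' or 'OS'")


def _angular_masks(angles: np.ndarray) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}
    # Half-annuli: strictly above / strictly below the horizontal meridian.
    masks["superior"] = (angles > 0.0) & (angles < 180.0)
    masks["inferior"] = angles > 180.0
    # Octants: center +/- 22.5 deg, half-open to partition the circle.
    for label, center in OCTANT_CENTERS.items():
        d = np.mod(angles - (center - 22.5), 360.0)
        masks[label] = d < 45.0
    return masks


def zone_masks(tmap: ThicknessMap, geom: ZoneGeometry) -> dict[str, np.ndarray]:
    """Boolean grid masks for every named zone."""
    r = tmap.grid.radii[:, None]
    in_central = np.broadcast_to(r <= geom.central_radius, tmap.values.shape)
    in_annulus = np.broadcast_to(
        (r > geom.annulus_inner) & (r <= geom.annulus_outer), tmap.values.shape
    )
    ang = _angular_masks(tmap.grid.angles)
    masks = {"central": in_central.copy()}
    for name in HALF_ZONES:
        masks[name] = in_annulus & ang[name][None, :]
    for name in OCTANT_CENTERS:
        masks[name] = in_annulus & ang[name][None, :]
    return masks


def zone_means(tmap: ThicknessMap, geom: ZoneGeometry | None = None) -> dict[str, float]:
    """Area-weighted mean thickness of every zone.

    Raises ``ValueError`` naming the zone if the grid is too coarse to put
    any point in it.
    """
    geom = geom or ZoneGeometry()
    w = tmap.grid.area_weights()
    out: dict[str, float] = {}
    for name, mask in zone_masks(tmap, geom).items():
        wm = w[mask]
        if wm.size == 0:
            raise ValueError(f"zone {name!r} contains no grid points")
        out[name] = float(np.average(tmap.values[mask], weights=wm))
    return out


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cutoff = 0.5 * cw[-1]
    return float(v[np.searchsorted(cw, cutoff)])


def _central_region(tmap: ThicknessMap, geom: ZoneGeometry):
    """Values, weights and (r, theta) of all grid points in the central
    5 mm (r <= annulus_outer)."""
    keep = tmap.grid.radii <= geom.annulus_outer
    vals = tmap.values[keep, :]
    w = tmap.grid.area_weights()[keep, :]
    r = np.broadcast_to(tmap.grid.radii[keep, None], vals.shape)
    t = np.broadcast_to(tmap.grid.theta[None, :], vals.shape)
    return vals.ravel(), w.ravel(), r.ravel(), t.ravel()


def _extremes(tmap: ThicknessMap, geom: ZoneGeometry):
    """(min, max, y_location_um) over the central 5 mm, vertex included.

    Arg-min ties are broken deterministically: smallest radius first, then
    smallest angle; the vertex (radius 0) precedes all grid points.
    """
    vals, _, r, t = _central_region(tmap, geom)
    vals = np.concatenate([[tmap.center_value], vals])
    r = np.concatenate([[0.0], r])
    t = np.concatenate([[0.0], t])
    ang = np.round(np.rad2deg(t), 9)
    imin = np.lexsort((ang, r, vals))[0]
    vmin = float(vals[imin])
    vmax = float(vals.max())
    y_um = float(r[imin] * np.sin(t[imin]) * 1000.0)
    return vmin, vmax, y_um


def pachymetry_features(tmap: ThicknessMap, geom: ZoneGeometry | None = None) -> dict[str, float]:
    """The seven pachymetry variables of an oriented map."""
    geom = geom or ZoneGeometry()
    zm = zone_means(tmap, geom)
    vals, w, _, _ = _central_region(tmap, geom)
    vmin, vmax, y_um = _extremes(tmap, geom)
    return {
        "SN_IT": zm["SN"] - zm["IT"],
        "Min": vmin,
        "Min_Med": vmin - _weighted_median(vals, w),
        "S_I": zm["superior"] - zm["inferior"],
        "Y_location": y_um,
        "Min_Max": vmin - vmax,
        "CCT": float(tmap.center_value),
    }


def epithelial_features(tmap: ThicknessMap, geom: ZoneGeometry | None = None) -> dict[str, float]:
    """The seven epithelial variables of an oriented map.

    ``SD`` is the area-weighted population standard deviation over all
    central-5 mm points.
    """
    geom = geom or ZoneGeometry()
    zm = zone_means(tmap, geom)
    vals, w, _, _ = _central_region(tmap, geom)
    vmin, vmax, _ = _extremes(tmap, geom)
    mean = np.average(vals, weights=w)
    sd = float(np.sqrt(np.average((vals - mean) ** 2, weights=w)))
    return {
        "Sup": zm["superior"],
        "Inf_ep": zm["inferior"],
        "Min_ep": vmin,
        "Max": vmax,
        "Min_Max_ep": vmin - vmax,
        "SD": sd,
        "CET": float(tmap.center_value),
    }


def extract_features(eye, geom: ZoneGeometry | None = None) -> dict[str, float]:
    """All fourteen variables of one :class:`~kcmap.synthetic.EyeRecord`.

    Maps are oriented before extraction, so left and right eyes are
    directly comparable.
    """
    geom = geom or ZoneGeometry()
    pachy = orient_map(eye.pachymetry, eye.side)
    epi = orient_map(eye.epithelium, eye.side)
    out = {"patient_id": eye.patient_id, "side": eye.side, "group": eye.group}
    out.update(pachymetry_features(pachy, geom))
    out.update(epithelial_features(epi, geom))
    return out


def extract_table(eyes, geom: ZoneGeometry | None = None) -> pd.DataFrame:
    """Feature table (one row per eye, id columns + the 14 variables)."""
    rows = [extract_features(e, geom) for e in eyes]
    cols = ["patient_id", "side", "group"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=cols)
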