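"""Topographic keratoconus screening criteria and study-group assignment.

Implements the four Placido-style screening indices on an anterior
surface power map and the rule that assigns each eye to one of the three
study groups:

* inferior-superior power asymmetry (I-S): mean surface power of 5
  inferior points minus 5 superior points, 3 mm from the center at
  30-degree intervals; keratoconus-positive at >= 1.4 D;
* central corneal power >= 47.2 D;
* KISA%: scaled product of central power, I-S, the astigmatism index AST
  and the skewed radial axis index SRAX; positive at >= 100%;
* KPI: a linear discriminant of quantitative topographic indices,
  positive at >= 0.23.  Its published coefficients are not available, so
  it ships disabled by default and accepts user-supplied coefficients.

An eye is labelled ``keratoconic`` if slit-lamp findings or any index
flag it; a topographically normal eye whose contralateral eye is
keratoconic is a ``fellow`` eye; anything else is ``normal``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import ThicknessMap

#: Inclusive decision thresholds of the four screening indices.
THRESHOLDS = {
    "is_index": 1.4,       # D
    "central_power": 47.2,  # D
    "kisa": 100.0,          # %
    "kpi": 0.23,
}

IS_INFERIOR_ANGLES = (210.0, 240.0, 270.0, 300.0, 330.0)
IS_SUPERIOR_ANGLES = (30.0, 60.0, 90.0, 120.0, 150.0)


@dataclass(frozen=True)
class TopoCriteria:
    """Computed screening indices and their threshold exceedances."""

    is_value: float
    central_power: float
    kisa_percent: float
    kpi: float | None = None

    @property
    def flags(self) -> dict[str, bool]:
        out = {
            "is_index": self.is_value >= THRESHOLDS["is_index"],
            "central_power": self.central_power >= THRESHOLDS["central_power"],
            "kisa": self.kisa_percent >= THRESHOLDS["kisa"],
        }
        if self.kpi is not None:
            out["kpi"] = self.kpi >= THRESHOLDS["kpi"]
        return out

    @property
    def any_flag(self) -> bool:
        return any(self.flags.values())


def _require_power(power_map: ThicknessMap | None) -> ThicknessMap:
    if power_map is None:
        raise ValueError("power map absent: topographic indices cannot be computed")
    return power_map


def sample_ring(power_map: ThicknessMap, radius_mm: float, angles_deg) -> np.ndarray:
    """Bilinear (radius x angle) interpolation of the map at given polar
    points."""
    grid = power_map.grid
    vals = power_map.values
    radii = grid.radii
    n_ang = grid.n_angles
    step = 360.0 / n_ang

    r = float(radius_mm)
    if r < radii[0] or r > radii[-1] + 1e-9:
        raise ValueError(f"radius {r} mm outside sampled range")
    j = int(np.clip(np.searchsorted(radii, r) - 1, 0, len(radii) - 2))
    fr = (r - radii[j]) / (radii[j + 1] - radii[j])
    fr = float(np.clip(fr, 0.0, 1.0))

    out = []
    for a in np.atleast_1d(np.asarray(angles_deg, dtype=float)):
        k = a % 360.0 / step
        k0 = int(np.floor(k)) % n_ang
        k1 = (k0 + 1) % n_ang
        fa = k - np.floor(k)
        v0 = vals[j, k0] * (1 - fa) + vals[j, k1] * fa
        v1 = vals[j + 1, k0] * (1 - fa) + vals[j + 1, k1] * fa
        out.append(v0 * (1 - fr) + v1 * fr)
    return np.array(out)


def is_index(power_map: ThicknessMap | None) -> float:
    """Inferior-superior power asymmetry (D) at the 3-mm ring."""
    pm = _require_power(power_map)
    inf = sample_ring(pm, 3.0, IS_INFERIOR_ANGLES).mean()
    sup = sample_ring(pm, 3.0, IS_SUPERIOR_ANGLES).mean()
    return float(inf - sup)


def central_power(power_map: ThicknessMap | None, radius_mm: float = 1.5) -> float:
    """Area-weighted mean power over the central zone (default 3-mm
    diameter; the averaging zone is not standardized and is exposed as a
    parameter)."""
    pm = _require_power(power_map)
    keep = pm.grid.radii <= radius_mm
    if not keep.any():
        raise ValueError("central power zone contains no grid points")
    w = pm.grid.area_weights()[keep, :]
    return float(np.average(pm.values[keep, :], weights=w))


def astigmatism_index(power_map: ThicknessMap | None, ring_radius_mm: float = 1.5) -> float:
    """AST: magnitude of regular corneal astigmatism (steep minus flat
    meridian power, D), from the second angular harmonic at a central
    ring."""
    pm = _require_power(power_map)
    theta = pm.grid.theta
    ring = sample_ring(pm, ring_radius_mm, pm.grid.angles)
    c = 2.0 * np.mean(ring * np.cos(2 * theta))
    s = 2.0 * np.mean(ring * np.sin(2 * theta))
    # amplitude of the cos(2t) component is half the steep-flat difference
    return float(2.0 * np.hypot(c, s))


def srax_index(power_map: ThicknessMap | None, ring_radius_mm: float = 1.5) -> float:
    """SRAX: skew (degrees) between the steep semi-meridian axes fitted
    in the superior and inferior half-rings; 0 for regular astigmatism
    whose axes are 180 degrees apart.

    Each half-ring axis comes from a least-squares second-harmonic fit
    (robust to measurement noise, unlike a raw arg-max over spokes)."""
    pm = _require_power(power_map)
    angles = pm.grid.angles
    theta = pm.grid.theta
    ring = sample_ring(pm, ring_radius_mm, angles)

    def steep_axis(mask) -> float:
        t, v = theta[mask], ring[mask]
        X = np.column_stack([np.ones(t.size), np.cos(2 * t), np.sin(2 * t)])
        _, b, c = np.linalg.lstsq(X, v, rcond=None)[0]
        return float(np.rad2deg(0.5 * np.arctan2(c, b)) % 180.0)

    sup = (angles > 0) & (angles < 180)
    inf = angles > 180
    if not sup.any() or not inf.any():
        raise ValueError("SRAX requires superior and inferior ring samples")
    d = abs(steep_axis(sup) - steep_axis(inf))
    return float(min(d, 180.0 - d))


def kisa(power_map: ThicknessMap | None, is_value: float | None = None) -> float:
    """KISA% = K * (I-S) * AST * SRAX / 300 * 100, each component from the
    power map.  A negative I-S (superior steeper) contributes 0, keeping
    the index non-negative."""
    pm = _require_power(power_map)
    k = central_power(pm)
    i_s = is_index(pm) if is_value is None else float(is_value)
    ast = astigmatism_index(pm)
    srax = srax_index(pm)
    return float(k * max(i_s, 0.0) * ast * srax / 300.0 * 100.0)


def kpi(index_values: np.ndarray | None, coefficients: np.ndarray | None) -> float | None:
    """Keratoconus predictability index: a linear discriminant over
    quantitative topographic indices.  Returns ``None`` when disabled
    (no coefficients supplied — the published ones are not available)."""
    if coefficients is None or index_values is None:
        return None
    x = np.asarray(index_values, dtype=float)
    c = np.asarray(coefficients, dtype=float)
    if c.size != x.size + 1:
        raise ValueError("KPI needs an intercept plus one coefficient per index")
    return float(c[0] + c[1:] @ x)


def evaluate_criteria(power_map: ThicknessMap | None) -> TopoCriteria:
    """All screening indices of one (oriented) power map."""
    pm = _require_power(power_map)
    i_s = is_index(pm)
    return TopoCriteria(
        is_value=i_s,
        central_power=central_power(pm),
        kisa_percent=kisa(pm, is_value=i_s),
    )


def classify_eye(criteria: TopoCriteria, slit_lamp_kc: bool, contralateral_kc: bool) -> str:
    """Study-group label of one eye.

    ``keratoconic`` when slit-lamp findings or any topographic criterion
    are positive; otherwise ``fellow`` if the contralateral eye is
    keratoconic, else ``normal``.
    """
    if slit_lamp_kc or criteria.any_flag:
        return "keratoconic"
    if contralateral_kc:
        return "fellow"
    return "normal"


def screen_cohort(eyes) -> pd.DataFrame:
    """Screen every eye of a cohort and assign study-group labels.

    The contralateral-keratoconus flag of each eye is derived from the
    classification of the patient's other eye (slit lamp or topographic
    positivity), mirroring how study groups are constructed clinically.
    """
    from .features import orient_map

    rows = []
    for eye in eyes:
        pm = orient_map(_require_power(eye.power), eye.side)
        crit = evaluate_criteria(pm)
        rows.append(
            {
                "patient_id": eye.patient_id,
                "side": eye.side,
                "group": eye.group,
                "slit_lamp_kc": eye.slit_lamp_kc,
                "is_value": crit.is_value,
                "central_power": crit.central_power,
                "kisa_percent": crit.kisa_percent,
                "kc_positive": eye.slit_lamp_kc or crit.any_flag,
            }
        )
    df = pd.DataFrame(rows)
    contra = (
        df.groupby("patient_id")["kc_positive"].transform("sum") - df["kc_positive"]
    ) > 0
    df["label"] = np.where(
        df["kc_positive"], "keratoconic", np.where(contra, "fellow", "normal")
    )
    return df
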