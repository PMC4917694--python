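"""Synthetic corneal-map cohort generator.

Produces per-eye pachymetry, epithelial and anterior-power maps with the
disease structure characteristic of keratoconus — a localized stromal
depression (the cone), an area of thinner epithelium over the cone
surrounded by an annulus of thicker epithelium, and surface steepening
proportional to the stromal depression — for three study groups:

* ``normal``       — both eyes of healthy subjects;
* ``keratoconic``  — the affected eye of an asymmetric-keratoconus patient;
* ``fellow``       — the topographically normal contralateral eye, modelled
  as an attenuated, inferiorly decentered cone.

The map model is, in the oriented frame (x temporal+, y superior+, mm):

    pachy(x, y) = t0 + k2*r^2 + k4*r^4 + gy*y + gx*x + noise
                  - depth * exp(-d^2 / (2*width^2))
    epi(x, y)   = e0 + ey*y + noise - thin * exp(-d^2 / (2*w_e^2))
                  + ann * exp(-(d - r_ann)^2 / (2*s_ann^2))
    power(x, y) = K + (ast/2)*cos(2*(theta - axis)) + noise
                  + c * depth * exp(-d^2 / (2*w_p^2))

with ``d`` the map-plane distance to the cone apex.  ``noise`` is a
low-order random harmonic surface (not white noise), so map extremes are
stable under grid refinement.

The per-group default parameter distributions (``DEFAULT_CALIBRATION``)
are moment-calibrated: the mean of every feature extracted from a large
generated cohort matches the published reference means in
:mod:`kcmap.reference`.  A per-eye latent severity ``z`` (standard
normal, correlated within patient at ``rho``) loads on the thickness
offsets and cone amplitudes, inducing realistic intra-patient
correlation.

A fast feature-level sampler (:func:`feature_sample`) draws the fourteen
variables directly from multivariate normals with the reference
means/SDs, bypassing map synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .maps import CalibrationError, PolarGrid, ThicknessMap, default_grid
from .reference import FEATURE_NAMES, REFERENCE_MOMENTS


# --------------------------------------------------------------------------
# types


@dataclass(frozen=True)
class ConeParams:
    """Geometry of the cone-like structural anomaly of one eye.

    Apex offsets are map-plane displacements from the vertex in um
    (matching the um convention of the thin-point location variable);
    widths and radii are in mm.
    """

    center_x_um: float = 0.0
    center_y_um: float = 0.0
    depth_um: float = 0.0          # maximal stromal depression
    width_mm: float = 0.9          # Gaussian radius of the depression
    epi_thinning_um: float = 0.0   # epithelial depression at the apex
    epi_width_mm: float = 0.8
    annulus_amp_um: float = 0.0    # annular epithelial thickening amplitude
    annulus_radius_mm: float = 1.8
    annulus_sigma_mm: float = 0.5

    def __post_init__(self):
        if self.depth_um < 0:
            raise ValueError("cone depth must be >= 0")
        if self.width_mm <= 0 or self.epi_width_mm <= 0 or self.annulus_sigma_mm <= 0:
            raise ValueError("cone widths must be > 0")
        if self.epi_thinning_um < 0 or self.annulus_amp_um < 0:
            raise ValueError("epithelial cone amplitudes must be >= 0")


@dataclass(frozen=True)
class EyeProfile:
    """Smooth-field parameters of one eye (everything but the cone)."""

    t0: float = 540.0            # pachymetry offset at the vertex (um)
    k2: float = 0.0              # peripheral thickening, quadratic (um/mm^2)
    k4: float = 0.0              # quartic correction (um/mm^4)
    grad_y: float = 0.0          # vertical pachymetry gradient (um/mm)
    grad_x: float = 0.0          # horizontal pachymetry gradient (um/mm)
    noise_p: float = 0.0         # pachymetry harmonic-noise RMS (um)
    e0: float = 53.0             # epithelial offset (um)
    egrad_y: float = 0.0         # vertical epithelial gradient (um/mm)
    noise_e: float = 0.0         # epithelial harmonic-noise RMS (um)
    k_base: float = 43.5         # central keratometry (D)
    astig: float = 0.0           # corneal astigmatism magnitude (D)
    astig_axis_deg: float = 90.0
    steep_per_um: float = 0.05   # surface steepening per um of depression (D/um)
    power_width_mm: float = 1.3
    noise_pow: float = 0.0       # power-map harmonic-noise RMS (D)


@dataclass(frozen=True)
class EyeRecord:
    """One synthetic eye: identifiers, group label and its maps.

    Maps are stored in the eye's native frame; apply
    :func:`kcmap.features.orient_map` before sector-labelled analysis.
    """

    patient_id: str
    side: str                     # "OD" | "OS"
    group: str                    # "normal" | "keratoconic" | "fellow"
    pachymetry: ThicknessMap
    epithelium: ThicknessMap
    power: ThicknessMap | None = None
    slit_lamp_kc: bool = False


class ParamSpec(NamedTuple):
    """Distribution of one generator parameter.

    ``value = mean + sd * (load * z + sqrt(1 - load^2) * eps)`` clipped to
    [lo, hi], where ``z`` is the eye's latent severity and ``eps`` an
    independent standard normal.
    """

    mean: float
    sd: float = 0.0
    load: float = 0.0
    lo: float = -np.inf
    hi: float = np.inf


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a cohort draw.

    ``rho`` is the intra-patient correlation of the latent severity; the
    source study does not report one, so it is a free parameter
    defaulting to 0.5.
    """

    n_normal_subjects: int = 52
    n_asym_kc_subjects: int = 22
    seed: int = 0
    rho: float = 0.5
    calibration: dict | None = None
    n_radii: int = 64
    n_angles: int = 128

    def __post_init__(self):
        if self.n_normal_subjects < 1 or self.n_asym_kc_subjects < 1:
            raise ValueError("subject counts must be >= 1")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")


# --------------------------------------------------------------------------
# default calibration
#
# Moment-calibrated so that features extracted from large generated
# cohorts reproduce the reference group means (thickness-valued features
# within 2%, difference/dispersion features within 15%).

PROFILE_PARAMS = (
    "t0", "k2", "k4", "grad_y", "grad_x", "noise_p",
    "e0", "egrad_y", "noise_e",
    "k_base", "astig", "astig_axis_deg", "steep_per_um", "power_width_mm", "noise_pow",
)
CONE_PARAMS = (
    "center_x_um", "center_y_um", "depth_um", "width_mm",
    "epi_thinning_um", "epi_width_mm",
    "annulus_amp_um", "annulus_radius_mm", "annulus_sigma_mm",
)

DEFAULT_CALIBRATION: dict[str, dict[str, ParamSpec]] = {
    "normal": {
        "t0": ParamSpec(551.8, 26.0, -0.5, 480.0, 600.0),
        "k2": ParamSpec(1.8, 0.3),
        "k4": ParamSpec(0.28, 0.04),
        "grad_y": ParamSpec(3.2, 1.2),
        "grad_x": ParamSpec(-3.4, 1.5),
        "noise_p": ParamSpec(3.5, 0.8, 0.0, 0.5, 8.0),
        "center_x_um": ParamSpec(0.0, 250.0),
        "center_y_um": ParamSpec(-18.0, 280.0, -0.2),
        "depth_um": ParamSpec(16.0, 4.0, 0.5, 0.0, 30.0),
        "width_mm": ParamSpec(0.8, 0.1, 0.0, 0.5, 1.5),
        "epi_thinning_um": ParamSpec(0.5, 0.5, 0.3, 0.0, 3.0),
        "epi_width_mm": ParamSpec(0.8, 0.1, 0.0, 0.4, 1.5),
        "annulus_amp_um": ParamSpec(0.3, 0.3, 0.0, 0.0, 2.0),
        "annulus_radius_mm": ParamSpec(1.8, 0.2, 0.0, 1.0, 2.4),
        "annulus_sigma_mm": ParamSpec(0.5, 0.1, 0.0, 0.2, 1.0),
        "e0": ParamSpec(52.8, 2.6, -0.3, 44.0, 70.0),
        "egrad_y": ParamSpec(-0.57, 0.25),
        "noise_e": ParamSpec(1.2, 0.3, 0.0, 0.2, 3.0),
        "k_base": ParamSpec(43.4, 1.1, 0.2, 40.0, 46.5),
        "astig": ParamSpec(0.9, 0.5, 0.0, 0.0, 3.0),
        "astig_axis_deg": ParamSpec(90.0, 40.0),
        "steep_per_um": ParamSpec(0.012, 0.003, 0.0, 0.0, 0.03),
        "power_width_mm": ParamSpec(1.3, 0.15, 0.0, 0.5, 2.5),
        "noise_pow": ParamSpec(0.10, 0.03, 0.0, 0.0, 0.25),
    },
    "fellow": {
        "t0": ParamSpec(528.0, 26.0, -0.5, 470.0, 600.0),
        "k2": ParamSpec(-2.95, 0.3),
        "k4": ParamSpec(0.78, 0.04),
        "grad_y": ParamSpec(4.9, 1.6),
        "grad_x": ParamSpec(-3.3, 1.8),
        "noise_p": ParamSpec(3.2, 0.8, 0.0, 0.5, 8.0),
        "center_x_um": ParamSpec(100.0, 250.0),
        "center_y_um": ParamSpec(-330.0, 330.0, -0.3),
        "depth_um": ParamSpec(24.0, 6.0, 0.6, 8.0, 45.0),
        "width_mm": ParamSpec(0.85, 0.1, 0.0, 0.5, 1.5),
        "epi_thinning_um": ParamSpec(1.4, 1.0, 0.4, 0.0, 6.0),
        "epi_width_mm": ParamSpec(0.8, 0.1, 0.0, 0.4, 1.5),
        "annulus_amp_um": ParamSpec(1.6, 0.8, 0.3, 0.0, 5.0),
        "annulus_radius_mm": ParamSpec(1.8, 0.2, 0.0, 1.0, 2.4),
        "annulus_sigma_mm": ParamSpec(0.5, 0.1, 0.0, 0.2, 1.0),
        "e0": ParamSpec(52.6, 3.0, -0.3, 45.0, 72.0),
        "egrad_y": ParamSpec(-0.1, 0.3),
        "noise_e": ParamSpec(1.6, 0.3, 0.0, 0.2, 3.5),
        "k_base": ParamSpec(43.6, 1.0, 0.2, 40.0, 45.9),
        "astig": ParamSpec(1.1, 0.6, 0.0, 0.0, 3.0),
        "astig_axis_deg": ParamSpec(90.0, 40.0),
        "steep_per_um": ParamSpec(0.008, 0.002, 0.0, 0.0, 0.02),
        "power_width_mm": ParamSpec(1.3, 0.15, 0.0, 0.5, 2.5),
        "noise_pow": ParamSpec(0.08, 0.02, 0.0, 0.0, 0.2),
    },
    "keratoconic": {
        "t0": ParamSpec(529.0, 24.0, -0.5, 480.0, 620.0),
        "k2": ParamSpec(2.0, 0.3),
        "k4": ParamSpec(-0.17, 0.04),
        "grad_y": ParamSpec(9.0, 3.0),
        "grad_x": ParamSpec(-3.5, 3.0),
        "noise_p": ParamSpec(4.0, 1.0, 0.0, 0.5, 9.0),
        "center_x_um": ParamSpec(100.0, 250.0),
        "center_y_um": ParamSpec(-780.0, 330.0, -0.4),
        "depth_um": ParamSpec(62.0, 22.0, 0.7, 25.0, 130.0),
        "width_mm": ParamSpec(1.15, 0.12, 0.0, 0.6, 1.7),
        "epi_thinning_um": ParamSpec(4.5, 2.5, 0.5, 1.5, 14.0),
        "epi_width_mm": ParamSpec(0.85, 0.1, 0.0, 0.4, 1.6),
        "annulus_amp_um": ParamSpec(11.1, 2.0, 0.4, 2.0, 18.0),
        "annulus_radius_mm": ParamSpec(1.9, 0.25, 0.0, 1.0, 2.4),
        "annulus_sigma_mm": ParamSpec(0.5, 0.08, 0.0, 0.2, 1.0),
        "e0": ParamSpec(48.65, 4.0, -0.3, 43.0, 68.0),
        "egrad_y": ParamSpec(1.75, 0.5),
        "noise_e": ParamSpec(2.8, 0.4, 0.0, 0.2, 4.0),
        "k_base": ParamSpec(45.5, 1.5, 0.3, 42.0, 50.0),
        "astig": ParamSpec(2.5, 1.2, 0.3, 0.3, 7.0),
        "astig_axis_deg": ParamSpec(90.0, 50.0),
        "steep_per_um": ParamSpec(0.09, 0.01, 0.2, 0.02, 0.2),
        "power_width_mm": ParamSpec(1.8, 0.2, 0.0, 0.8, 2.8),
        "noise_pow": ParamSpec(0.25, 0.08, 0.0, 0.0, 0.8),
    },
}


# --------------------------------------------------------------------------
# smooth harmonic noise

# (radial power, angular harmonic) pairs of the random-surface basis
_NOISE_TERMS = [(1, 1), (2, 1), (1, 2), (2, 2), (2, 0), (1, 3)]

_BASIS_CACHE: dict[tuple, np.ndarray] = {}


def _noise_basis(grid: PolarGrid) -> np.ndarray:
    """Stack of smooth basis surfaces, each normalized to unit
    area-weighted RMS over the central 5 mm."""
    key = (grid.n_radii, grid.n_angles, grid.radii.tobytes())
    cached = _BASIS_CACHE.get(key)
    if cached is not None:
        return cached
    r = grid.radii[:, None] / 2.5
    t = grid.theta[None, :]
    fields = []
    for p, q in _NOISE_TERMS:
        if q == 0:
            fields.append(r ** p * np.ones_like(t))
        else:
            fields.append(r ** p * np.cos(q * t))
            fields.append(r ** p * np.sin(q * t))
    basis = np.stack(fields)
    w = grid.area_weights()
    keep = grid.radii <= 2.5
    wc = w[keep, :]
    for i in range(basis.shape[0]):
        rms = np.sqrt(np.average(basis[i, keep, :] ** 2, weights=wc))
        basis[i] /= rms
    _BASIS_CACHE[key] = basis
    return basis


def smooth_noise(grid: PolarGrid, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order random harmonic surface with area-weighted RMS ~ sigma
    over the central 5 mm."""
    basis = _noise_basis(grid)
    if sigma == 0:
        # keep the rng stream aligned whether or not noise is active
        rng.standard_normal(basis.shape[0])
        return np.zeros((grid.n_radii, grid.n_angles))
    coef = rng.standard_normal(basis.shape[0]) * (sigma / np.sqrt(basis.shape[0]))
    return np.tensordot(coef, basis, axes=1)


# --------------------------------------------------------------------------
# single-eye synthesis


def _cone_distance2(grid: PolarGrid, cone: ConeParams) -> np.ndarray:
    x, y = grid.mesh()
    return (x - cone.center_x_um / 1000.0) ** 2 + (y - cone.center_y_um / 1000.0) ** 2


def generate_eye(
    profile: EyeProfile,
    cone: ConeParams,
    rng: np.random.Generator,
    *,
    patient_id: str = "P0000",
    side: str = "OD",
    group: str = "normal",
    slit_lamp_kc: bool = False,
    grid: PolarGrid | None = None,
) -> EyeRecord:
    """Synthesize one eye from a smooth-field profile and cone geometry.

    The fields are built in the oriented frame and mirrored for left
    eyes, so the stored maps are in the eye's native frame.  Raises
    :class:`~kcmap.maps.CalibrationError` if the parameters drive any
    thickness outside its physical bounds.
    """
    grid = grid or default_grid()
    x, y = grid.mesh()
    r2 = x ** 2 + y ** 2
    d2 = _cone_distance2(grid, cone)
    cone_g = np.exp(-d2 / (2.0 * cone.width_mm ** 2))
    rc2 = (cone.center_x_um / 1000.0) ** 2 + (cone.center_y_um / 1000.0) ** 2

    pachy = (
        profile.t0
        + profile.k2 * r2
        + profile.k4 * r2 ** 2
        + profile.grad_y * y
        + profile.grad_x * x
        + smooth_noise(grid, profile.noise_p, rng)
        - cone.depth_um * cone_g
    )
    pachy_center = profile.t0 - cone.depth_um * np.exp(-rc2 / (2.0 * cone.width_mm ** 2))

    d = np.sqrt(d2)
    epi_cone = np.exp(-d2 / (2.0 * cone.epi_width_mm ** 2))
    ring = np.exp(-((d - cone.annulus_radius_mm) ** 2) / (2.0 * cone.annulus_sigma_mm ** 2))
    rc = np.sqrt(rc2)
    epi = (
        profile.e0
        + profile.egrad_y * y
        + smooth_noise(grid, profile.noise_e, rng)
        - cone.epi_thinning_um * epi_cone
        + cone.annulus_amp_um * ring
    )
    epi_center = (
        profile.e0
        - cone.epi_thinning_um * np.exp(-rc2 / (2.0 * cone.epi_width_mm ** 2))
        + cone.annulus_amp_um
        * np.exp(-((rc - cone.annulus_radius_mm) ** 2) / (2.0 * cone.annulus_sigma_mm ** 2))
    )

    steep = profile.steep_per_um * cone.depth_um
    power = (
        profile.k_base
        + 0.5 * profile.astig * np.cos(2.0 * (grid.theta[None, :] - np.deg2rad(profile.astig_axis_deg)))
        + smooth_noise(grid, profile.noise_pow, rng)
        + steep * np.exp(-d2 / (2.0 * profile.power_width_mm ** 2))
    )
    power_center = profile.k_base + steep * np.exp(-rc2 / (2.0 * profile.power_width_mm ** 2))

    try:
        pachy_map = ThicknessMap(grid, pachy, float(pachy_center), tag="pachymetry")
        epi_map = ThicknessMap(grid, epi, float(epi_center), tag="epithelium")
    except CalibrationError as err:
        raise CalibrationError(
            f"{err} (group={group!r}, t0={profile.t0:.1f}, e0={profile.e0:.1f}, "
            f"depth={cone.depth_um:.1f}, epi_thinning={cone.epi_thinning_um:.1f})"
        ) from err
    power_map = ThicknessMap(grid, power, float(power_center), tag="power")

    if side == "OS":
        pachy_map = pachy_map.mirrored()
        epi_map = epi_map.mirrored()
        power_map = power_map.mirrored()
    elif side != "OD":
        raise ValueError(f"unknown eye side {side!r}")

    return EyeRecord(
        patient_id=patient_id,
        side=side,
        group=group,
        pachymetry=pachy_map,
        epithelium=epi_map,
        power=power_map,
        slit_lamp_kc=slit_lamp_kc,
    )


def _draw_value(spec: ParamSpec, z: float, rng: np.random.Generator) -> float:
    if spec.sd == 0:
        value = spec.mean
    else:
        eps = rng.standard_normal()
        value = spec.mean + spec.sd * (spec.load * z + np.sqrt(1.0 - spec.load ** 2) * eps)
    return float(np.clip(value, spec.lo, spec.hi))


def draw_parameters(
    calibration: dict[str, ParamSpec], z: float, rng: np.random.Generator
) -> tuple[EyeProfile, ConeParams]:
    """Draw one eye's (profile, cone) from a group calibration at latent
    severity ``z``."""
    values = {name: _draw_value(spec, z, rng) for name, spec in calibration.items()}
    profile = EyeProfile(**{k: values[k] for k in PROFILE_PARAMS})
    cone = ConeParams(**{k: values[k] for k in CONE_PARAMS})
    return profile, cone


def draw_eye(
    calibration: dict[str, ParamSpec],
    z: float,
    rng: np.random.Generator,
    *,
    max_retries: int = 100,
    **eye_kwargs,
) -> EyeRecord:
    """Draw parameters and synthesize one eye, redrawing on physical-bound
    rejections.

    Extreme joint tail draws (roughly 1 in 2,000 at the default
    calibration) can push a map outside its physical bounds;
    :func:`generate_eye` rejects those.  This wrapper resamples the
    parameters (at the same latent severity) until a valid eye results,
    which is ordinary rejection sampling from the truncated parameter
    distribution.
    """
    for _ in range(max_retries):
        profile, cone = draw_parameters(calibration, z, rng)
        try:
            return generate_eye(profile, cone, rng, **eye_kwargs)
        except CalibrationError:
            continue
    raise CalibrationError(
        f"no physically valid eye in {max_retries} draws; "
        "the calibration is incompatible with the physical bounds"
    )


def _merged_calibration(overrides: dict | None) -> dict[str, dict[str, ParamSpec]]:
    if not overrides:
        return DEFAULT_CALIBRATION
    merged = {g: dict(params) for g, params in DEFAULT_CALIBRATION.items()}
    for group, params in overrides.items():
        if group not in merged:
            raise ValueError(f"unknown calibration group {group!r}")
        for name, spec in params.items():
            if name not in merged[group]:
                raise ValueError(f"unknown calibration parameter {name!r}")
            merged[group][name] = ParamSpec(*spec)
    return merged


def generate_cohort(spec: CohortSpec) -> list[EyeRecord]:
    """Generate a full two-eyes-per-subject cohort.

    Healthy subjects contribute two normal eyes; asymmetric-keratoconus
    subjects contribute one keratoconic and one fellow eye (affected side
    randomized).  Latent severities of the two eyes of a patient are
    correlated at ``spec.rho``.  Fully reproducible given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = default_grid(spec.n_radii, spec.n_angles)
    calib = _merged_calibration(spec.calibration)
    rho = spec.rho
    records: list[EyeRecord] = []

    def eye_severities() -> tuple[float, float]:
        u = rng.standard_normal()
        e1, e2 = rng.standard_normal(2)
        a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
        return float(a * u + b * e1), float(a * u + b * e2)

    pid = 0
    for _ in range(spec.n_normal_subjects):
        pid += 1
        z_od, z_os = eye_severities()
        for side, z in (("OD", z_od), ("OS", z_os)):
            records.append(
                draw_eye(
                    calib["normal"], z, rng,
                    patient_id=f"P{pid:04d}", side=side, group="normal", grid=grid,
                )
            )
    for _ in range(spec.n_asym_kc_subjects):
        pid += 1
        z_kc, z_fe = eye_severities()
        kc_side = "OD" if rng.random() < 0.5 else "OS"
        for side in ("OD", "OS"):
            if side == kc_side:
                group, slit, z = "keratoconic", True, z_kc
            else:
                group, slit, z = "fellow", False, z_fe
            records.append(
                draw_eye(
                    calib[group], z, rng,
                    patient_id=f"P{pid:04d}", side=side, group=group,
                    slit_lamp_kc=slit, grid=grid,
                )
            )
    return records


# --------------------------------------------------------------------------
# fast feature-level sampler


def feature_sample(
    group: str,
    n: int,
    rng: np.random.Generator,
    corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw ``n`` feature vectors directly from a multivariate normal with
    the group's reference means and SDs (independent coordinates unless a
    correlation matrix is given)."""
    if group not in REFERENCE_MOMENTS:
        raise ValueError(f"unknown group {group!r}")
    means = np.array([REFERENCE_MOMENTS[group][f][0] for f in FEATURE_NAMES])
    sds = np.array([REFERENCE_MOMENTS[group][f][1] for f in FEATURE_NAMES])
    k = len(FEATURE_NAMES)
    if n == 0:
        return pd.DataFrame(columns=FEATURE_NAMES, dtype=float)
    if corr is None:
        draws = means + sds * rng.standard_normal((n, k))
    else:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")
        cov = np.outer(sds, sds) * corr
        draws = rng.multivariate_normal(means, cov, size=n, method="eigh")
    return pd.DataFrame(draws, columns=FEATURE_NAMES)
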