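"""Published reference moments for the fourteen OCT map variables.

These are the group-level summary statistics (mean, SD, median, range) of
the fourteen pachymetry and epithelial map variables reported for an
asymmetric-keratoconus OCT cohort: 104 normal eyes of healthy subjects,
and 22 keratoconic plus 22 topographically normal fellow eyes of 22
patients with highly asymmetric keratoconus.  They serve two purposes in
this package:

* the default calibration target of the synthetic map generator
  (:mod:`kcmap.synthetic`), and
* the parameter source for the fast feature-level sampler
  (:func:`kcmap.synthetic.feature_sample`).

All thickness-valued variables are in micrometres; ``Y_location`` is a
signed vertical map-plane offset in micrometres (negative = inferior to
the vertex).
"""

from __future__ import annotations

#: Canonical column order of the fourteen diagnostic variables.
FEATURE_NAMES = [
    "SN_IT",        # superonasal minus inferotemporal pachymetry, 2-5 mm annulus
    "Min",          # minimum pachymetry over the central 5 mm
    "Min_Med",      # minimum minus median pachymetry
    "S_I",          # superior minus inferior pachymetry, 2-5 mm annulus
    "Y_location",   # vertical offset of the thinnest point (um, + superior)
    "Min_Max",      # minimum minus maximum pachymetry
    "CCT",          # central corneal thickness
    "Sup",          # mean superior epithelium, 2-5 mm annulus
    "Inf_ep",       # mean inferior epithelium, 2-5 mm annulus
    "Min_ep",       # minimum epithelial thickness
    "Max",          # maximum epithelial thickness
    "Min_Max_ep",   # minimum minus maximum epithelial thickness
    "SD",           # standard deviation of epithelial thickness, central 5 mm
    "CET",          # central epithelial thickness
]

#: Pachymetry-map subset of :data:`FEATURE_NAMES`.
PACHYMETRY_FEATURES = FEATURE_NAMES[:7]

#: Epithelial-map subset of :data:`FEATURE_NAMES`.
EPITHELIAL_FEATURES = FEATURE_NAMES[7:]

GROUPS = ["normal", "fellow", "keratoconic"]

#: group -> feature -> (mean, sd, median, (range_min, range_max))
REFERENCE_MOMENTS = {
    "normal": {
        "SN_IT":      (17.39, 12.92, 17.0, (-24.0, 54.0)),
        "Min":        (531.7, 30.17, 532.0, (454.0, 592.0)),
        "Min_Med":    (-20.50, 5.06, -20.0, (-47.0, -8.0)),
        "S_I":        (8.519, 12.70, 9.0, (-40.0, 48.0)),
        "Y_location": (-155.9, 398.43, -141.0, (-1370.0, 607.0)),
        "Min_Max":    (-53.42, 11.81, -52.0, (-97.0, -26.0)),
        "CCT":        (537.6, 30.66, 538.0, (459.0, 598.0)),
        "Sup":        (52.03, 3.27, 52.0, (37.0, 60.0)),
        "Inf_ep":     (53.38, 3.10, 53.0, (46.0, 62.0)),
        "Min_ep":     (49.52, 3.73, 50.0, (33.0, 57.0)),
        "Max":        (56.0, 3.55, 56.0, (48.0, 69.0)),
        "Min_Max_ep": (-6.423, 3.04, -6.0, (-25.0, -2.0)),
        "SD":         (1.549, 0.75, 1.40, (0.6, 4.9)),
        "CET":        (52.90, 3.09, 53.0, (42.0, 61.0)),
    },
    "fellow": {
        "SN_IT":      (24.50, 20.05, 20.0, (-1.0, 68.0)),
        "Min":        (503.2, 32.71, 499.5, (447.0, 597.0)),
        "Min_Med":    (-22.36, 9.42, -20.5, (-48.0, -13.0)),
        "S_I":        (15.950, 17.35, 15.0, (-19.0, 48.0)),
        "Y_location": (-558.6, 591.70, -610.0, (-1809.0, 513.0)),
        "Min_Max":    (-57.50, 18.80, -52.5, (-103.0, -37.0)),
        "CCT":        (513.1, 31.90, 512.5, (453.0, 605.0)),
        "Sup":        (53.27, 4.25, 52.0, (48.0, 67.0)),
        "Inf_ep":     (53.14, 4.50, 52.5, (47.0, 70.0)),
        "Min_ep":     (49.09, 4.74, 49.0, (37.0, 64.0)),
        "Max":        (56.86, 4.52, 56.5, (52.0, 73.0)),
        "Min_Max_ep": (-7.818, 3.89, -6.0, (-20.0, -3.0)),
        "SD":         (1.891, 0.99, 1.50, (0.7, 4.7)),
        "CET":        (52.0, 4.07, 53.23, (49.0, 68.0)),
    },
    "keratoconic": {
        "SN_IT":      (56.95, 28.49, 55.0, (12.0, 114.0)),
        "Min":        (458.0, 45.14, 451.5, (380.0, 589.0)),
        "Min_Med":    (-54.27, 23.72, -51.0, (-101.0, -14.0)),
        "S_I":        (44.770, 35.25, 41.0, (-38.0, 115.0)),
        "Y_location": (-947.5, 549.53, -834.0, (-2369.0, -206.0)),
        "Min_Max":    (-114.60, 51.96, -99.0, (-227.0, -44.0)),
        "CCT":        (482.9, 30.62, 479.0, (416.0, 536.0)),
        "Sup":        (55.55, 6.36, 55.0, (40.0, 67.0)),
        "Inf_ep":     (50.82, 5.86, 49.5, (41.0, 64.0)),
        "Min_ep":     (41.18, 6.45, 42.0, (33.0, 56.0)),
        "Max":        (63.36, 8.45, 62.0, (47.0, 80.0)),
        "Min_Max_ep": (-22.090, 10.80, -20.0, (-44.0, -7.0)),
        "SD":         (5.918, 3.19, 5.55, (1.7, 13.8)),
        "CET":        (48.59, 5.71, 47.5, (39.0, 61.0)),
    },
}

#: Study group sizes (eyes): 52 healthy subjects x 2 eyes, 22 asymmetric
#: keratoconus patients contributing one keratoconic and one fellow eye.
STUDY_SIZES = {"normal": 104, "fellow": 22, "keratoconic": 22}


def group_mean_sd(group: str, feature: str) -> tuple[float, float]:
    """Return the reference (mean, sd) of ``feature`` in ``group``."""
    mean, sd, _, _ = REFERENCE_MOMENTS[group][feature]
    return mean, sd


def group_means(group: str) -> dict[str, float]:
    """Reference means of all fourteen variables for ``group``."""
    return {f: REFERENCE_MOMENTS[group][f][0] for f in FEATURE_NAMES}
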