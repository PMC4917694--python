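"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (python loops,
explicit enumeration) and must stay independent of the implementation
paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def enum_zone_stats(tmap, geom):
    """Cell-enumeration zone means, weighted median/variance and extremes
    over the central 5 mm, by looping over every grid point."""
    zones = {
        "central": [], "superior": [], "inferior": [],
        "T": [], "ST": [], "S": [], "SN": [], "N": [], "IN": [], "I": [], "IT": [],
    }
    octant_centers = {"T": 0, "ST": 45, "S": 90, "SN": 135, "N": 180,
                      "IN": 225, "I": 270, "IT": 315}
    central = []  # (value, weight, r, angle)
    for i, r in enumerate(tmap.grid.radii):
        for j, a in enumerate(tmap.grid.angles):
            v = float(tmap.values[i, j])
            w = float(r)
            if r <= geom.annulus_outer:
                central.append((v, w, float(r), float(a)))
            if r <= geom.central_radius:
                zones["central"].append((v, w))
            if geom.annulus_inner < r <= geom.annulus_outer:
                if 0 < a < 180:
                    zones["superior"].append((v, w))
                if a > 180:
                    zones["inferior"].append((v, w))
                for name, c in octant_centers.items():
                    d = (a - (c - 22.5)) % 360.0
                    if d < 45.0:
                        zones[name].append((v, w))
    means = {}
    for name, pts in zones.items():
        sw = sum(w for _, w in pts)
        means[name] = sum(v * w for v, w in pts) / sw if pts else math.nan

    # weighted median: first value whose cumulative weight reaches half
    pts = sorted(central, key=lambda t: t[0])
    total = sum(p[1] for p in pts)
    acc, med = 0.0, pts[-1][0]
    for v, w, _, _ in pts:
        acc += w
        if acc >= 0.5 * total:
            med = v
            break

    # two-pass weighted variance
    mean = sum(v * w for v, w, _, _ in central) / total
    var = sum(w * (v - mean) ** 2 for v, w, _, _ in central) / total

    # extremes with vertex candidate; ties: smallest radius, then angle
    cands = [(float(tmap.center_value), 0.0, 0.0)] + [
        (v, r, a) for v, _, r, a in central
    ]
    vmin, rmin, amin = min(cands, key=lambda t: (t[0], t[1], t[2]))
    vmax = max(c[0] for c in cands)
    y_um = rmin * math.sin(math.radians(amin)) * 1000.0
    return {
        "zone_means": means, "median": med, "sd": math.sqrt(var),
        "min": vmin, "max": vmax, "y_location": y_um,
    }


def pair_count_auc(scores, labels):
    """Exhaustive pair enumeration AUC (larger score => positive)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos = s[y]
    neg = s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def midranks(values):
    """Hand-rolled midranks (average rank for ties)."""
    v = list(values)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_h(values, groups):
    """Tie-corrected Kruskal-Wallis H from explicitly enumerated ranks."""
    v = list(values)
    g = list(groups)
    n = len(v)
    r = midranks(v)
    h = 0.0
    for lab in set(g):
        idx = [i for i in range(n) if g[i] == lab]
        rs = sum(r[i] for i in idx)
        h += rs * rs / len(idx)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for x in v:
        counts[x] = counts.get(x, 0) + 1
    tie = sum(c ** 3 - c for c in counts.values())
    denom = 1.0 - tie / (n ** 3 - n)
    if denom == 0:
        return 0.0
    return h / denom


def ecdf_ks_stat(values, cdf):
    """Max |ECDF - F| by enumeration at every sample point (both sides)."""
    v = sorted(values)
    n = len(v)
    d = 0.0
    for i, x in enumerate(v):
        f = cdf(x)
        d = max(d, abs((i + 1) / n - f), abs(i / n - f))
    return d
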