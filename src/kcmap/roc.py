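"""ROC/AUC machinery with patient-cluster awareness.

The empirical AUC is the Mann-Whitney estimator (concordant pairs plus
half the ties over all diseased-healthy pairs).  Because the two eyes of
a patient are correlated, the standard error of the AUC is estimated by
a leave-one-cluster-out jackknife over patients rather than an
observation-level formula; the 95% CI is Wald (auc +/- 1.96*SE), reported
both untruncated and truncated to [0, 1].

Markers are auto-oriented so the reported AUC is >= 0.5 on the data it
was computed from, with the direction retained in ``orientation`` (+1:
larger marker values indicate disease; -1: smaller values do).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

Z95 = 1.959963984540054


@dataclass(frozen=True)
class AUCResult:
    auc: float
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_low_raw: float | None = None     # untruncated Wald bounds
    ci_high_raw: float | None = None
    orientation: int = 1
    n_pos: int = 0
    n_neg: int = 0
    n_clusters: int | None = None


def _validate(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def _auc_oriented(s: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC of `larger score => positive` with midrank ties."""
    r = rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def empirical_auc(scores, labels, orientation: int | None = None) -> AUCResult:
    """Empirical (pair-counting) AUC point estimate.

    ``orientation`` fixes the marker direction; by default it is chosen
    so the AUC is >= 0.5.
    """
    s, y = _validate(scores, labels)
    a = _auc_oriented(s, y)
    if orientation is None:
        orientation = 1 if a >= 0.5 else -1
    if orientation == -1:
        a = 1.0 - a
    return AUCResult(auc=a, orientation=orientation,
                     n_pos=int(y.sum()), n_neg=int((~y).sum()))


def clustered_auc_ci(scores, labels, cluster_ids) -> AUCResult:
    """AUC with cluster-aware (patient-level) jackknife CI.

    The SE is the leave-one-cluster-out jackknife over patients; with
    every cluster of size one this reduces to the ordinary delete-one
    jackknife.  The orientation is fixed on the full data and kept for
    all jackknife replicates.
    """
    s, y = _validate(scores, labels)
    c = np.asarray(cluster_ids)
    if c.shape != s.shape:
        raise ValueError("cluster_ids must match scores")
    uniq = np.unique(c)
    if uniq.size < 2:
        raise ValueError("variance undefined with a single cluster")

    point = empirical_auc(s, y)
    orient = point.orientation

    thetas = []
    for g in uniq:
        keep = c != g
        yk = y[keep]
        if yk.all() or not yk.any():
            raise ValueError(
                f"removing cluster {g!r} leaves a single class; "
                "jackknife SE is undefined"
            )
        thetas.append(empirical_auc(s[keep], yk, orientation=orient).auc)
    thetas = np.asarray(thetas)
    G = uniq.size
    se = float(np.sqrt((G - 1) / G * np.sum((thetas - thetas.mean()) ** 2)))

    lo_raw, hi_raw = point.auc - Z95 * se, point.auc + Z95 * se
    return AUCResult(
        auc=point.auc, se=se,
        ci_low=max(0.0, lo_raw), ci_high=min(1.0, hi_raw),
        ci_low_raw=lo_raw, ci_high_raw=hi_raw,
        orientation=orient, n_pos=point.n_pos, n_neg=point.n_neg,
        n_clusters=int(G),
    )


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Analytic AUC of two normal score distributions:
    Phi(|mu_pos - mu_neg| / sqrt(sd_pos^2 + sd_neg^2))."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf(abs(mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))


def roc_points(scores, labels, orientation: int | None = None) -> "np.ndarray":
    """ROC curve vertices (FPR, TPR) at every distinct threshold, after
    orientation; returns an (m, 2) array from (0,0) to (1,1)."""
    s, y = _validate(scores, labels)
    if orientation is None:
        orientation = empirical_auc(s, y).orientation
    if orientation == -1:
        s = -s
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = tp / y.sum()
    fpr = fp / (~y).sum()
    return np.vstack([np.r_[0.0, fpr], np.r_[0.0, tpr]]).T
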