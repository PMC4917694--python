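"""Study-replica orchestration: simulate -> extract -> screen -> stats -> roc.

A run is a pure function of its :class:`RunConfig`: the same config
(including seed) reproduces the same report bundle byte for byte (the
manifest records a timestamp but it is excluded from the config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import extract_table
from .gam import gam_transform, glm_combine, monotonicity_check
from .io import write_features_csv, write_maps_csv
from .reference import FEATURE_NAMES
from .roc import clustered_auc_ci, roc_points
from .stats import ks_normality, summarize, test_features
from .synthetic import CohortSpec, generate_cohort
from .topo import screen_cohort

log = logging.getLogger("kcmap")

#: The three pairwise group comparisons, as (diseased, reference).
COMPARISONS = [
    ("keratoconic", "normal"),
    ("keratoconic", "fellow"),
    ("fellow", "normal"),
]

#: Combined logistic models per comparison: uncorrelated informative
#: variables for the keratoconic contrasts, all variables for the
#: fellow-vs-normal contrast.  Min_Max_ep is excluded from the
#: all-variable model: on extracted maps it equals Min_ep - Max exactly,
#: which would make the design rank-deficient.
COMBINED_MODELS = {
    ("keratoconic", "normal"): ["Min_Med", "S_I", "Min_ep"],
    ("keratoconic", "fellow"): ["SD", "CCT"],
    ("fellow", "normal"): [f for f in FEATURE_NAMES if f != "Min_Max_ep"],
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one study-replica run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    holm: bool = False           # Holm-adjust post hoc p-values
    truncate_ci: bool = True     # report CI truncated to [0, 1]
    use_gam: bool = True         # transform non-monotone markers
    write_maps: bool = False     # full long-format map export (large)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, cfg: dict, seed: int | None = None) -> "RunConfig":
        cohort_keys = {
            "n_normal_subjects", "n_asym_kc_subjects", "seed", "rho",
            "calibration", "n_radii", "n_angles",
        }
        ckw = {k: v for k, v in cfg.items() if k in cohort_keys}
        if seed is not None:
            ckw["seed"] = int(seed)
        other = {k: v for k, v in cfg.items() if k not in cohort_keys}
        unknown = set(other) - {"holm", "truncate_ci", "use_gam", "write_maps", "log_level"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=CohortSpec(**ckw), **other)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def auc_table(
    features: pd.DataFrame,
    pos_group: str,
    neg_group: str,
    columns: list[str] | None = None,
    use_gam: bool = True,
    truncate_ci: bool = True,
) -> pd.DataFrame:
    """Per-variable cluster-adjusted AUC for one group contrast.

    Markers whose smooth risk relationship is non-monotone are replaced
    by their GAM-estimated disease probability before the ROC analysis
    (flagged in the ``transformed`` column).
    """
    columns = columns or [c for c in FEATURE_NAMES if c in features.columns]
    sub = features[features["group"].isin([pos_group, neg_group])]
    y = (sub["group"] == pos_group).to_numpy()
    clusters = sub["patient_id"].to_numpy()
    rows = []
    for col in columns:
        x = sub[col].to_numpy(dtype=float)
        transformed = False
        if use_gam and x.size >= 20 and not monotonicity_check(x, y).monotone:
            x = gam_transform(x, y)(x)
            transformed = True
        res = clustered_auc_ci(x, y, clusters)
        lo = res.ci_low if truncate_ci else res.ci_low_raw
        hi = res.ci_high if truncate_ci else res.ci_high_raw
        rows.append(
            {"variable": col, "auc": res.auc, "se": res.se, "ci_low": lo,
             "ci_high": hi, "orientation": res.orientation,
             "transformed": transformed}
        )
    return pd.DataFrame(rows)


def combined_auc(
    features: pd.DataFrame,
    pos_group: str,
    neg_group: str,
    columns: list[str],
    truncate_ci: bool = True,
) -> tuple[pd.Series, np.ndarray]:
    """Cluster-adjusted in-sample AUC of a logistic combination; returns
    the summary row and the ROC curve vertices of the combined marker."""
    sub = features[features["group"].isin([pos_group, neg_group])]
    y = (sub["group"] == pos_group).to_numpy()
    model = glm_combine(sub, y, columns)
    score = model.linear_predictor(sub)
    res = clustered_auc_ci(score, y, sub["patient_id"].to_numpy())
    lo = res.ci_low if truncate_ci else res.ci_low_raw
    hi = res.ci_high if truncate_ci else res.ci_high_raw
    row = pd.Series(
        {"comparison": f"{pos_group} vs {neg_group}",
         "variables": "+".join(columns), "auc": res.auc, "se": res.se,
         "ci_low": lo, "ci_high": hi, "ridged": model.ridged}
    )
    return row, roc_points(score, y, orientation=res.orientation)


def run_study(config: RunConfig, out_dir) -> dict:
    """Execute the full replica pipeline and write the report bundle.

    Writes: cohort roster, feature table, screening table, Table-1-style
    summary, normality checks, hypothesis tests, per-variable AUC tables
    for the three pairwise comparisons, combined-model AUCs with ROC
    curve points, and a run manifest.  Returns the tables in a dict.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort)
        log.info("simulate: %d eyes in %.1fs", len(cohort), time.time() - t0)

        stage = "extract"
        features = extract_table(cohort)
        write_features_csv(features, out / "features.csv")
        roster = features[["patient_id", "side", "group"]]
        roster.to_csv(out / "cohort.csv", index=False)
        if config.write_maps:
            write_maps_csv(cohort, out / "maps.csv")

        stage = "screen"
        screen = screen_cohort(cohort)
        screen.to_csv(out / "screen.csv", index=False, float_format="%.6g")

        stage = "stats"
        summary = summarize(features)
        summary.to_csv(out / "summary.csv", index=False, float_format="%.6g")
        normality = pd.DataFrame(
            [
                {"group": g, "feature": f, **dict(zip(("statistic", "p_value"),
                 ks_normality(sub[f])))}
                for g, sub in features.groupby("group", sort=False)
                for f in FEATURE_NAMES
            ]
        )
        normality.to_csv(out / "normality.csv", index=False, float_format="%.6g")
        tests = test_features(features, holm=config.holm)
        tests.to_csv(out / "tests.csv", index=False, float_format="%.6g")

        stage = "roc"
        combined_rows = []
        for pos, neg in COMPARISONS:
            tbl = auc_table(features, pos, neg, use_gam=config.use_gam,
                            truncate_ci=config.truncate_ci)
            tbl.to_csv(out / f"auc_{pos}_vs_{neg}.csv", index=False,
                       float_format="%.6g")
            row, curve = combined_auc(features, pos, neg,
                                      COMBINED_MODELS[(pos, neg)],
                                      truncate_ci=config.truncate_ci)
            combined_rows.append(row)
            pd.DataFrame(curve, columns=["fpr", "tpr"]).to_csv(
                out / f"roc_combined_{pos}_vs_{neg}.csv", index=False,
                float_format="%.6g")
        combined = pd.DataFrame(combined_rows)
        combined.to_csv(out / "auc_combined.csv", index=False, float_format="%.6g")
    except Exception:
        log.exception("stage %r failed", stage)
        raise

    manifest = {
        "package": "kcmap",
        "version": __version__,
        "seed": config.cohort.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_eyes": len(cohort),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.info("run complete in %.1fs -> %s", time.time() - t0, out)
    return {
        "features": features, "screen": screen, "summary": summary,
        "normality": normality, "tests": tests, "combined": combined,
    }
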