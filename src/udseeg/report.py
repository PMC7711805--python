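"""Per-channel nonparametric class comparison and report emission.

``channel_comparison`` reproduces the channel-statistics table: per channel
the class-conditional SampEn mean/SD and a two-sided Mann-Whitney U test
(asymptotic, tie- and continuity-corrected) between the two states, with a
significance flag at 0.05.  Bonferroni- and Benjamini-Hochberg-adjusted
p-values are emitted as extra columns but do not drive the flag, matching
the uncorrected presentation convention of the per-channel table.

``make_report`` serializes the benchmark deterministically: metric grids
(one row per classifier, before/after PCA), per-fold metric series, ROC
points, the channel table and a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .classify import CVResult
from .containers import FeatureMatrix
from .profiles import NUDS, UDS

__all__ = ["channel_comparison", "make_report"]

_FLOAT_FMT = "%.6f"


def channel_comparison(features: FeatureMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Class comparison of every channel; one row per channel, montage order.

    Columns: channel, uds_mean/sd, nuds_mean/sd, u_stat (U of the UDS
    sample), p_value (two-sided, normal approximation with tie and
    continuity corrections), significant (p < alpha), p_bonferroni, p_fdr.
    Channels that are constant and identical across both classes have no
    defined test; their p is NaN and never flagged significant.
    """
    uds = features.rows_for(UDS)
    nuds = features.rows_for(NUDS)
    if len(uds) == 0 or len(nuds) == 0:
        raise ValueError("both classes must be present")
    rows = []
    for j, ch in enumerate(features.channel_labels):
        a, b = uds[:, j], nuds[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            u, p = np.nan, np.nan
        else:
            res = sstats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            u, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "channel": ch,
                "uds_mean": float(a.mean()),
                "uds_sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                "nuds_mean": float(b.mean()),
                "nuds_sd": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
                "u_stat": u,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    valid = df["p_value"].notna()
    df["significant"] = valid & (df["p_value"] < alpha)
    df["p_bonferroni"] = np.nan
    df["p_fdr"] = np.nan
    if valid.any():
        pvals = df.loc[valid, "p_value"].to_numpy()
        df.loc[valid, "p_bonferroni"] = np.minimum(pvals * valid.sum(), 1.0)
        df.loc[valid, "p_fdr"] = multipletests(pvals, method="fdr_bh")[1]
    return df


def _metrics_grid(cv_results: dict[str, dict[str, CVResult]]) -> pd.DataFrame:
    """Classifier x (feature set) grid of pooled percent metrics and AUC."""
    rows = []
    for feature_set, per_clf in cv_results.items():
        for name, res in per_clf.items():
            m = res.pooled_metrics
            rows.append(
                {
                    "feature_set": feature_set,
                    "classifier": name,
                    "ACC": m.acc,
                    "SEN": m.sen,
                    "SPE": m.spe,
                    "PRE": m.pre,
                    "AUC": res.roc.auc,
                }
            )
    return pd.DataFrame(rows)


def _fold_series(cv_results: dict[str, dict[str, CVResult]]) -> pd.DataFrame:
    rows = []
    for feature_set, per_clf in cv_results.items():
        for name, res in per_clf.items():
            for f, m in enumerate(res.fold_metrics, start=1):
                rows.append(
                    {
                        "feature_set": feature_set,
                        "classifier": name,
                        "fold": f,
                        "ACC": m.acc,
                        "SEN": m.sen,
                        "SPE": m.spe,
                        "PRE": m.pre,
                    }
                )
    return pd.DataFrame(rows)


def _roc_points(cv_results: dict[str, dict[str, CVResult]]) -> pd.DataFrame:
    rows = []
    for feature_set, per_clf in cv_results.items():
        for name, res in per_clf.items():
            for fpr, tpr in zip(res.roc.fpr, res.roc.tpr):
                rows.append(
                    {
                        "feature_set": feature_set,
                        "classifier": name,
                        "fpr": float(fpr),
                        "tpr": float(tpr),
                    }
                )
    return pd.DataFrame(rows)


def make_report(
    cv_results: dict[str, dict[str, CVResult]],
    comparison: pd.DataFrame,
    out_dir,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Write the benchmark report; returns the emitted paths by name.

    ``cv_results`` maps a feature-set name (e.g. ``"sampen"``,
    ``"sampen+pca"``) to {classifier name -> CVResult}.  All files are
    written with fixed float formatting and sorted JSON keys, so
    regenerating a report from the same inputs is byte-identical.
    """
    if not cv_results or comparison is None or len(comparison) == 0:
        raise ValueError("report inputs must be nonempty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paths = {
        "metrics": out / "classifier_metrics.csv",
        "folds": out / "fold_metrics.csv",
        "roc": out / "roc_points.csv",
        "channels": out / "channel_comparison.csv",
        "manifest": out / "manifest.json",
    }
    _metrics_grid(cv_results).to_csv(paths["metrics"], index=False, float_format=_FLOAT_FMT)
    _fold_series(cv_results).to_csv(paths["folds"], index=False, float_format=_FLOAT_FMT)
    _roc_points(cv_results).to_csv(paths["roc"], index=False, float_format=_FLOAT_FMT)
    comparison.to_csv(paths["channels"], index=False, float_format=_FLOAT_FMT)

    manifest = {
        "feature_sets": {
            fs: {
                name: {
                    "pooled_confusion": {
                        "tp": res.pooled_confusion.tp,
                        "fn": res.pooled_confusion.fn,
                        "fp": res.pooled_confusion.fp,
                        "tn": res.pooled_confusion.tn,
                    },
                    "auc": round(res.roc.auc, 6),
                    "pca_mode": res.config.pca_mode,
                    "n_folds": res.config.n_folds,
                    "seed": res.config.seed,
                }
                for name, res in per_clf.items()
            }
            for fs, per_clf in cv_results.items()
        },
        "n_channels": int(len(comparison)),
        "n_significant_channels": int(comparison["significant"].sum()),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths
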