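"""Field-effect correlation statistics with FDR control.

Two test families quantify the radial texture gradient around a tumor:

* **Kendall's Tau-b** between the ordinal ROI region (0 = tumor, 1 = near,
  2 = far) and each feature, per modality.  Tau-b is the tie-corrected rank
  correlation, appropriate because the region variable has massive ties.
* **Pearson's rho** between mammogram and specimen feature values over
  matched (patient, region) ROI pairs, pooling regions.

Every family is corrected with the Benjamini-Hochberg step-up procedure at
a configurable FDR (default 5%).  The family size m is the number of
features actually tested: features whose statistic is undefined (all-NaN or
constant values) are excluded before the correction, which is conservative
for the discovery count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_roi import REGION_ORDINAL

__all__ = [
    "CorrelationTable",
    "kendall_tau_b",
    "pearson",
    "bh_adjust",
    "region_association",
    "cross_modality_association",
    "build_report",
]


@dataclass
class CorrelationTable:
    """Per-feature statistics for one (family, test, modality) combination."""

    table: pd.DataFrame  # index = feature names
    family: str  # "radiomic" | "deep"
    test: str  # "tau_b_mammo" | "tau_b_specimen" | "pearson"
    fdr: float = 0.05
    n_tested: int = field(default=0)


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def kendall_tau_b(region_ordinal, values) -> tuple[float, float]:
    """Tie-corrected Kendall rank correlation between an ordinal grouping and
    a numeric feature; p-value from the tie-aware normal approximation.

    Returns (nan, nan) when the statistic is undefined (n < 3, a single
    region level, or all values tied); such features are excluded from BH.
    """
    x, y = _clean_pairs(region_ordinal, values)
    if x.size < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
        return (np.nan, np.nan)
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return (float(res.statistic), float(res.pvalue))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation; two-sided p from the t transform with
    n-2 degrees of freedom.  NaN rows are dropped pairwise; zero variance in
    either vector -> (nan, nan), excluded from BH."""
    x, y = _clean_pairs(x, y)
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return (np.nan, np.nan)
    res = stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


def bh_adjust(p_values, fdr: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags.

    Finds the largest rank k with p(k) <= (k/m) * fdr (m = len(p_values),
    i.e. the family of features actually tested) and flags every p <= p(k).
    NaN p-values are never flagged and do not count toward m.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, np.float64)
    if p.size == 0:
        return np.zeros(0, bool)
    flags = np.zeros(p.size, bool)
    ok = ~np.isnan(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=fdr, method="fdr_bh")[0]
    return flags


def region_association(
    features: pd.DataFrame,
    regions,
    family: str = "radiomic",
    modality: str = "mammo",
    fdr: float = 0.05,
) -> CorrelationTable:
    """One Tau-b test per feature column against the ordinal region, BH
    corrected within this (family, modality) test set.

    ``regions`` may be raw labels (A/B/C/D; C and D pool to "far") or
    already-ordinal integers.
    """
    ordinal = np.asarray(
        [REGION_ORDINAL[r] if isinstance(r, str) else int(r) for r in regions]
    )
    if len(ordinal) != len(features):
        raise ValueError("features and regions must be row-aligned")
    rows = {}
    for name in features.columns:
        tau, p = kendall_tau_b(ordinal, features[name].to_numpy())
        rows[name] = {"tau_b": tau, "p": p}
    tab = pd.DataFrame.from_dict(rows, orient="index")
    tab["sig"] = bh_adjust(tab["p"].to_numpy(), fdr=fdr)
    return CorrelationTable(
        table=tab, family=family, test=f"tau_b_{modality}", fdr=fdr,
        n_tested=int(tab["p"].notna().sum()),
    )


def cross_modality_association(
    mammo_features: pd.DataFrame,
    specimen_features: pd.DataFrame,
    family: str = "radiomic",
    fdr: float = 0.05,
) -> CorrelationTable:
    """One Pearson test per feature over matched ROI rows (both frames must
    be aligned row-for-row on the same (patient, region) pairs, regions
    pooled), BH corrected within the family."""
    if list(mammo_features.columns) != list(specimen_features.columns):
        raise ValueError("feature columns must match between modalities")
    if len(mammo_features) != len(specimen_features):
        raise ValueError("matched feature frames must have equal row counts")
    if len(mammo_features) < 3:
        raise ValueError("need at least 3 matched ROI pairs for Pearson correlation")
    rows = {}
    for name in mammo_features.columns:
        rho, p = pearson(mammo_features[name].to_numpy(), specimen_features[name].to_numpy())
        rows[name] = {"rho": rho, "p": p}
    tab = pd.DataFrame.from_dict(rows, orient="index")
    tab["sig"] = bh_adjust(tab["p"].to_numpy(), fdr=fdr)
    return CorrelationTable(
        table=tab, family=family, test="pearson", fdr=fdr,
        n_tested=int(tab["p"].notna().sum()),
    )


def match_modalities(
    features: pd.DataFrame,
    feature_names,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a long feature table (patient_id, modality, region, features...)
    into row-aligned mammo/specimen frames over the matched (patient, region)
    pairs present in both modalities."""
    key = ["patient_id", "region"]
    mam = features[features["modality"] == "mammo"].set_index(key)
    spc = features[features["modality"] == "specimen"].set_index(key)
    common = mam.index.intersection(spc.index)
    cols = list(feature_names)
    return mam.loc[common, cols].reset_index(drop=True), spc.loc[common, cols].reset_index(drop=True)


def build_report(
    tables: list[CorrelationTable],
    out_dir: str | Path,
    heatmap: bool = False,
) -> dict[str, Path]:
    """Write one CSV per family combining its test columns, mirroring the
    published table convention: statistic, raw p, BH flag, and an asterisk
    column ('*' where significant at the family FDR).

    With ``heatmap=True`` also renders ``<family>_heatmap.png`` with a
    diverging color scale saturating at |0.5|.
    """
    if not tables:
        raise ValueError("at least one correlation table is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    by_family: dict[str, list[CorrelationTable]] = {}
    for t in tables:
        by_family.setdefault(t.family, []).append(t)

    for family, fam_tables in by_family.items():
        merged = None
        for t in fam_tables:
            stat_col = "tau_b" if t.test.startswith("tau_b") else "rho"
            sub = t.table.rename(
                columns={stat_col: f"{t.test}_{stat_col}", "p": f"{t.test}_p",
                         "sig": f"{t.test}_sig"}
            )
            sub[f"{t.test}_asterisk"] = np.where(sub[f"{t.test}_sig"], "*", "")
            merged = sub if merged is None else merged.join(sub, how="outer")
        path = out / f"{family}_correlations.csv"
        merged.to_csv(path, index_label="feature")
        written[family] = path

        if heatmap:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            stat_cols = [c for c in merged.columns if c.endswith(("_tau_b", "_rho"))]
            data = merged[stat_cols].to_numpy(np.float64)
            fig, ax = plt.subplots(figsize=(4 + len(stat_cols), max(4, 0.25 * len(merged))))
            im = ax.imshow(data, cmap="RdYlGn", vmin=-0.5, vmax=0.5, aspect="auto")
            ax.set_xticks(range(len(stat_cols)), stat_cols, rotation=45, ha="right")
            ax.set_yticks(range(len(merged)), merged.index, fontsize=6)
            for j, col in enumerate(stat_cols):
                sig_col = col.rsplit("_", 1)[0] + "_sig" if col.endswith("_rho") else col[: -len("_tau_b")] + "_sig"
                for i, flag in enumerate(merged[sig_col].fillna(False)):
                    if flag:
                        ax.text(j, i, "*", ha="center", va="center", fontsize=7)
            fig.colorbar(im, ax=ax, shrink=0.6)
            fig.tight_layout()
            hpath = out / f"{family}_heatmap.png"
            fig.savefig(hpath, dpi=120)
            plt.close(fig)
            written[f"{family}_heatmap"] = hpath
    return written
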