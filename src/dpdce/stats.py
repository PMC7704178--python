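"""Cohort-level biomarker statistics for the IDH-mutation discrimination study.

Per-patient parameter medians are pooled into a cohort table (one row per
patient, one column per kinetic parameter plus the binary IDH label), on
which the full statistical battery operates: Shapiro–Wilk normality
checks, two-sided Wilcoxon rank-sum group comparisons, Spearman
correlations between Tofts and DP parameters, and ROC analysis with the
Youden-index cutoff (maximal sensitivity + specificity).

The positive class throughout is IDH-mutant.  Since mutant gliomas show
lower perfusion/permeability values for most parameters, the ROC
orientation (whether values below or above the cutoff call a mutant) is
auto-detected and recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RocResult",
    "pool_patient_medians",
    "wilcoxon_rank_sum",
    "shapiro_wilk",
    "spearman",
    "roc_youden",
    "accuracy_from_rates",
    "build_report",
    "TOFTS_REPORT_PARAMS",
    "DP_REPORT_PARAMS",
]

TOFTS_REPORT_PARAMS = ("tofts_ktrans", "tofts_ve", "tofts_kep")
DP_REPORT_PARAMS = ("dp_f", "dp_ps", "dp_e", "dp_ve", "dp_vp")


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def pool_patient_medians(patients: dict, labels: dict, masks: dict | None = None) -> pd.DataFrame:
    """Build the cohort table of per-patient parameter medians.

    Parameters
    ----------
    patients : dict
        ``patient_id -> {column_name: values}`` where values are the
        per-voxel parameter estimates of that patient (arrays; NaN entries
        — failed voxels — are ignored).  `ParameterMaps` instances are also
        accepted; their in-mask voxels are flattened (column names gain the
        model prefix).
    labels : dict
        ``patient_id -> group label`` (e.g. "mutant"/"wildtype").
    masks : dict, optional
        ``patient_id -> bool array`` restricting map-valued inputs.

    Patients without a single valid voxel in some parameter get NaN there;
    patients with no valid voxels at all are dropped.
    """
    rows = []
    for pid, data in patients.items():
        if hasattr(data, "maps"):  # ParameterMaps
            mask = None if masks is None else masks.get(pid)
            data = {
                f"{data.model}_{name}": (vol[mask] if mask is not None else vol.ravel())
                for name, vol in data.maps.items()
            }
        row = {"patient_id": pid, "group": labels[pid]}
        any_valid = False
        for col, values in data.items():
            values = np.asarray(values, dtype=float)
            valid = values[np.isfinite(values)]
            row[col] = float(np.median(valid)) if valid.size else np.nan
            any_valid = any_valid or valid.size > 0
        if any_valid:
            rows.append(row)
    df = pd.DataFrame(rows)
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicated patient ids")
    return df


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration for small tie-free samples (both n ≤ 20), otherwise
    the tie-corrected normal approximation with continuity correction.
    Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def shapiro_wilk(x) -> float:
    """Shapiro–Wilk normality p-value (3 ≤ n ≤ 5000; constant input errors)."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(x == x[0]):
        raise ValueError("degenerate constant sample")
    return float(sps.shapiro(x).pvalue)


def spearman(x, y):
    """Spearman rank correlation ``(r, p)``; constant inputs give (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """ROC summary: AUC, Youden-optimal cutoff and operating point (%).

    ``positive_below`` records the orientation: True when values below the
    cutoff call the positive (mutant) class.
    """

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    positive_below: bool
    n_pos: int
    n_neg: int


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + ½·P(pos = neg) via midranks (tie-corrected)."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return u / (pos.size * neg.size)


def roc_youden(values, labels, positive="mutant", orientation="auto") -> RocResult:
    """ROC analysis with the Youden-index cutoff.

    AUC is the Mann–Whitney probability (tie-corrected), oriented so that
    AUC ≥ 0.5 when ``orientation="auto"``.  Candidate cutoffs are the
    midpoints between adjacent distinct observed values (plus the all-one-
    side extremes); the cutoff maximizing sensitivity + specificity wins,
    ties broken toward higher specificity.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive
    pos, neg = values[is_pos], values[~is_pos]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    auc_above = _mann_whitney_auc(pos, neg)  # P(pos > neg), "above calls positive"
    if orientation == "auto":
        positive_below = auc_above < 0.5
    elif orientation in ("below", "above"):
        positive_below = orientation == "below"
    else:
        raise ValueError("orientation must be 'auto', 'below' or 'above'")
    auc = 1.0 - auc_above if positive_below else auc_above

    distinct = np.unique(values)
    cutoffs = np.concatenate([
        [distinct[0] - 1.0],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 1.0],
    ])
    best = None
    for cut in cutoffs:
        call_pos = values < cut if positive_below else values > cut
        sens = 100.0 * np.mean(call_pos[is_pos])
        spec = 100.0 * np.mean(~call_pos[~is_pos])
        key = (sens + spec, spec)
        if best is None or key > best[0]:
            best = (key, cut, sens, spec)
    _, cutoff, sens, spec = best
    acc = 100.0 * (sens / 100.0 * pos.size + spec / 100.0 * neg.size) / values.size
    return RocResult(
        auc=float(auc),
        cutoff=float(cutoff),
        sensitivity=float(sens),
        specificity=float(spec),
        accuracy=float(acc),
        positive_below=bool(positive_below),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def accuracy_from_rates(sensitivity: float, specificity: float,
                        n_pos: int, n_neg: int) -> float:
    """Accuracy (%) implied by printed sensitivity/specificity and group sizes.

    Printed rates are rounded from integer confusion-matrix counts, so the
    rates are first converted to the nearest achievable counts:
    accuracy = (TP + TN)/(n_pos + n_neg).
    """
    tp = round(sensitivity / 100.0 * n_pos)
    tn = round(specificity / 100.0 * n_neg)
    return 100.0 * (tp + tn) / (n_pos + n_neg)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def _iqr_str(values: np.ndarray) -> str:
    q25, q75 = np.nanpercentile(values, [25, 75])
    return f"{q25:.2f}-{q75:.2f}"


def build_report(cohort: pd.DataFrame, positive: str = "mutant") -> dict:
    """Produce the three study-style summary tables from a cohort table.

    Returns a dict of DataFrames:

    * ``medians`` — per-parameter group medians, IQRs and Wilcoxon p;
    * ``diagnostics`` — AUC, Youden cutoff, sensitivity/specificity/accuracy;
    * ``correlations`` — Spearman r (p) of Tofts Ktrans and Ve against the
      DP parameters, per group.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValueError("cohort must contain exactly two groups")
    negative = next(g for g in groups if g != positive)
    param_cols = [c for c in cohort.columns if c not in ("patient_id", "group")]

    med_rows, diag_rows = [], []
    for col in param_cols:
        sub = cohort[["group", col]].dropna()
        a = sub.loc[sub["group"] == positive, col].to_numpy()
        b = sub.loc[sub["group"] == negative, col].to_numpy()
        med_rows.append({
            "parameter": col,
            f"median_{positive}": np.median(a),
            f"iqr_{positive}": _iqr_str(a),
            f"median_{negative}": np.median(b),
            f"iqr_{negative}": _iqr_str(b),
            "wilcoxon_p": wilcoxon_rank_sum(a, b),
        })
        roc = roc_youden(sub[col].to_numpy(), sub["group"].to_numpy(), positive)
        diag_rows.append({
            "parameter": col,
            "auc": roc.auc,
            "cutoff": roc.cutoff,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "accuracy": roc.accuracy,
            "positive_below": roc.positive_below,
        })

    corr_rows = []
    tofts_cols = [c for c in ("tofts_ktrans", "tofts_ve") if c in param_cols]
    dp_cols = [c for c in DP_REPORT_PARAMS if c in param_cols]
    for grp in (positive, negative):
        sub = cohort[cohort["group"] == grp]
        for dcol in dp_cols:
            row = {"group": grp, "dp_parameter": dcol}
            for tcol in tofts_cols:
                pair = sub[[tcol, dcol]].dropna()
                if len(pair) >= 3:
                    r, p = spearman(pair[tcol].to_numpy(), pair[dcol].to_numpy())
                else:
                    r, p = np.nan, np.nan
                row[f"r_{tcol}"] = r
                row[f"p_{tcol}"] = p
            corr_rows.append(row)

    return {
        "medians": pd.DataFrame(med_rows),
        "diagnostics": pd.DataFrame(diag_rows),
        "correlations": pd.DataFrame(corr_rows),
    }
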