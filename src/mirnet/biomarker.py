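"""Two-group biomarker statistics and ROC evaluation of circulating levels.

Implements the clinical-statistics conventions of the study design: a
Shapiro-Wilk normality gate choosing between a t-test and the Mann-Whitney
U-test, fold change as the ratio of group medians, ROC analysis with a
Youden-index reporting cutoff (case = positive class, level above threshold
= test-positive), median-split subgrouping on a covariate such as aneurysm
diameter, and Spearman rank correlation of levels with covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InputError

__all__ = [
    "read_biomarker_table",
    "compare_groups",
    "roc",
    "ROCResult",
    "subgroup_by_median",
    "correlate",
]

_SHAPIRO_MAX_N = 5000


def read_biomarker_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("subject_id", "group", "level"):
        if col not in table.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return table


def _group_levels(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    case = table.loc[table["group"] == "case", "level"].to_numpy(float)
    ctrl = table.loc[table["group"] == "control", "level"].to_numpy(float)
    return case, ctrl


def compare_groups(table: pd.DataFrame,
                   alpha_normality: float = 0.05,
                   fold: str = "median") -> dict:
    """Normality-gated two-group comparison of biomarker levels.

    Both groups passing Shapiro-Wilk at ``alpha_normality`` selects Welch's
    t-test; otherwise the tie-corrected Mann-Whitney U-test. Fold change is
    median(case)/median(control) (mean ratio via ``fold='mean'``). Groups
    larger than 5000 default to the nonparametric branch.
    """
    case, ctrl = _group_levels(table)
    if len(case) < 3 or len(ctrl) < 3:
        raise InputError("each group needs >= 3 subjects")
    if (case <= 0).any() or (ctrl <= 0).any():
        raise InputError("levels must be positive")
    if max(len(case), len(ctrl)) > _SHAPIRO_MAX_N:
        normal = False
    else:
        normal = (stats.shapiro(case).pvalue > alpha_normality
                  and stats.shapiro(ctrl).pvalue > alpha_normality)
    if normal:
        res = stats.ttest_ind(case, ctrl, equal_var=False)
        test_used = "welch_t"
    else:
        res = stats.mannwhitneyu(case, ctrl, alternative="two-sided")
        test_used = "mannwhitney"
    agg = np.median if fold == "median" else np.mean
    return {
        "test_used": test_used,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "fold_change": float(agg(case) / agg(ctrl)),
        "n_case": len(case),
        "n_control": len(ctrl),
    }


@dataclass
class ROCResult:
    """ROC sweep over observed levels with trapezoidal AUC and Youden cutoff."""

    thresholds: np.ndarray
    sensitivity: np.ndarray   # TPR per threshold
    specificity: np.ndarray   # 1 - FPR per threshold
    auc: float
    youden_threshold: float
    sensitivity_at_youden: float
    specificity_at_youden: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})

    def summary(self) -> dict:
        return {"auc": self.auc,
                "youden_threshold": self.youden_threshold,
                "sensitivity_at_youden": self.sensitivity_at_youden,
                "specificity_at_youden": self.specificity_at_youden}


def roc(table: pd.DataFrame) -> ROCResult:
    """ROC analysis of levels with case as the positive class.

    AUC is the trapezoidal area under TPR vs FPR (numerically identical to
    the tie-corrected Mann-Whitney U divided by n1*n2). The Youden threshold
    maximizes sensitivity + specificity - 1; ties break toward higher
    specificity.
    """
    case, ctrl = _group_levels(table)
    if len(case) == 0 or len(ctrl) == 0:
        raise InputError("both groups must be non-empty")
    y = np.concatenate([np.ones(len(case)), np.zeros(len(ctrl))])
    scores = np.concatenate([case, ctrl])
    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    best = best[np.argmin(fpr[best])]  # ties -> higher specificity
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        youden_threshold=float(thresholds[best]),
        sensitivity_at_youden=float(tpr[best]),
        specificity_at_youden=float(1.0 - fpr[best]),
    )


def subgroup_by_median(table: pd.DataFrame, covariate: str
                       ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split cases at the case-group median of a covariate.

    The cutpoint is the median of the covariate among cases; cases with
    covariate <= cutpoint form the low group, the rest the high group.
    """
    cases = table.loc[table["group"] == "case"]
    if covariate not in table.columns:
        raise InputError(f"covariate {covariate!r} not present")
    missing = cases.loc[cases[covariate].isna(), "subject_id"].tolist()
    if missing:
        raise InputError(
            f"missing {covariate!r} for subjects: {missing}")
    cut = float(cases[covariate].median())
    low = cases.loc[cases[covariate] <= cut]
    high = cases.loc[cases[covariate] > cut]
    return low, high, cut


def correlate(table: pd.DataFrame, covariate: str) -> tuple[float, float]:
    """Spearman rank correlation of level vs a covariate (mid-ranks for ties).

    Rows with a missing covariate are excluded; at least 4 complete pairs are
    required, and a constant input leaves rho undefined (input error).
    """
    if covariate not in table.columns:
        raise InputError(f"covariate {covariate!r} not present")
    sub = table.loc[table[covariate].notna(), ["level", covariate]]
    if len(sub) < 4:
        raise InputError("need >= 4 paired observations")
    x = sub["level"].to_numpy(float)
    y = sub[covariate].to_numpy(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InputError("constant input: Spearman rho undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
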