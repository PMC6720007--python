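"""Detection filtering, differential expression and PCA for miRNA arrays.

The expression stage mirrors standard two-color-free miRNA microarray
practice: probes must beat the negative-control signal in enough samples to
count as detected; differential expression is a per-miRNA two-sample test on
log2 signal with Benjamini-Hochberg FDR adjustment; candidates must clear a
q-value, fold-change, and mean-expression cutoff simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA

from .errors import InputError

__all__ = [
    "ExpressionMatrix",
    "detection_filter",
    "differential_expression",
    "benjamini_hochberg",
    "pca",
    "collapse_probes",
    "read_series_matrix",
]

DEFAULT_Q_MAX = 0.05
DEFAULT_FC_MIN = 0.5
DEFAULT_EXPR_MIN = 5.0


@dataclass
class ExpressionMatrix:
    """Probes/miRNAs x samples log2 signal with group labels.

    ``values`` rows are probe or miRNA ids, columns sample ids;
    ``groups`` maps each sample to 'case' or 'control';
    ``negative_control_mask`` flags control-probe rows.
    """

    values: pd.DataFrame
    groups: pd.Series
    negative_control_mask: pd.Series

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InputError(f"duplicate row id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise InputError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.reindex(self.values.columns)
        self.negative_control_mask = self.negative_control_mask.reindex(
            self.values.index, fill_value=False)
        counts = self.groups.value_counts()
        for g in ("case", "control"):
            if counts.get(g, 0) < 2:
                raise InputError(f"group {g!r} has fewer than 2 samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def split_groups(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        case = self.values.loc[:, (self.groups == "case").values]
        ctrl = self.values.loc[:, (self.groups == "control").values]
        return case, ctrl

    def drop_negative_controls(self) -> "ExpressionMatrix":
        keep = ~self.negative_control_mask
        return ExpressionMatrix(self.values.loc[keep.values],
                                self.groups,
                                self.negative_control_mask.loc[keep.values])

    # ---- I/O (synthdata TSV dialect) ----
    def to_tsv(self, matrix_path: str | Path, samples_path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "is_negative_control",
                   self.negative_control_mask.astype(int).values)
        out.to_csv(matrix_path, sep="\t", index_label="probe_id")
        self.groups.rename("group").to_frame().to_csv(
            samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 samples_path: str | Path) -> "ExpressionMatrix":
        raw = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        if "group" not in samples.columns:
            raise InputError(f"{samples_path}: missing 'group' column")
        if "is_negative_control" in raw.columns:
            mask = raw.pop("is_negative_control").astype(bool)
        else:
            mask = pd.Series(False, index=raw.index)
        return cls(values=raw, groups=samples["group"],
                   negative_control_mask=mask)


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read the data table of a GEO series-matrix TSV.

    Metadata lines are prefixed with '!'; the numeric table sits between the
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` markers.
    Returns probes x samples values; group labels must be supplied separately.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise InputError(f"{path}: series-matrix table markers not found")
    from io import StringIO
    table = pd.read_csv(StringIO("\n".join(lines[start + 1:end])), sep="\t",
                        index_col=0)
    table.index.name = "probe_id"
    return table


def collapse_probes(matrix: ExpressionMatrix,
                    probe_to_mirna: pd.Series) -> ExpressionMatrix:
    """Collapse multiple probes per miRNA by the per-sample median signal.

    Probes absent from the map keep their own id. Negative-control rows are
    never collapsed.
    """
    keep_nc = matrix.negative_control_mask
    ids = matrix.values.index.to_series()
    mapped = ids.where(keep_nc, ids.map(probe_to_mirna).fillna(ids))
    collapsed = matrix.values.groupby(mapped.values).median()
    nc_ids = set(ids[keep_nc.values])
    mask = pd.Series([i in nc_ids for i in collapsed.index],
                     index=collapsed.index)
    return ExpressionMatrix(collapsed, matrix.groups, mask)


def detection_filter(matrix: ExpressionMatrix,
                     min_sample_frac: float = 0.5,
                     negctrl_quantile: float = 0.9) -> ExpressionMatrix:
    """Keep miRNAs detected above the negative-control level in enough samples.

    A miRNA counts as detected in a sample when its signal exceeds the
    ``negctrl_quantile`` quantile of that sample's negative-control probe
    signals; it is retained when detected in at least ``min_sample_frac`` of
    samples. Negative-control rows are removed from the output.
    """
    nc = matrix.values.loc[matrix.negative_control_mask.values]
    if nc.empty:
        raise InputError("matrix has no negative-control rows")
    thresholds = nc.quantile(negctrl_quantile, axis=0)
    signal = matrix.values.loc[~matrix.negative_control_mask.values]
    detected_frac = (signal.gt(thresholds, axis=1)).mean(axis=1)
    keep = detected_frac >= min_sample_frac
    kept = signal.loc[keep.values]
    return ExpressionMatrix(kept, matrix.groups,
                            pd.Series(False, index=kept.index))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; order-preserving in
    the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(matrix: ExpressionMatrix,
                            method: str = "welch_t",
                            q_max: float = DEFAULT_Q_MAX,
                            fc_min: float = DEFAULT_FC_MIN,
                            expr_min: float = DEFAULT_EXPR_MIN) -> pd.DataFrame:
    """Per-miRNA two-sample testing with BH adjustment and the three cutoffs.

    log2FC is the case-minus-control mean of log2 signal; ``passes_cutoffs``
    requires q < q_max, |log2FC| > fc_min and mean expression > expr_min
    simultaneously. The detection filter is assumed already applied.

    Parameters
    ----------
    method : {'welch_t', 'mannwhitney'}
        Welch's unequal-variance t-test (default) or the tie-corrected
        Mann-Whitney U-test with normal approximation.
    """
    if matrix.negative_control_mask.any():
        matrix = matrix.drop_negative_controls()
    case, ctrl = matrix.split_groups()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise InputError("each group needs >= 2 samples")
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    mean_expr = matrix.values.mean(axis=1)
    if method == "welch_t":
        res = stats.ttest_ind(case.values, ctrl.values, axis=1,
                              equal_var=False)
        p = res.pvalue
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(case.values, ctrl.values, axis=1,
                                 alternative="two-sided", method="asymptotic")
        p = res.pvalue
    else:
        raise InputError(f"unknown method {method!r}")
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance rows
    q = benjamini_hochberg(p)
    table = pd.DataFrame({
        "mean_expression": mean_expr,
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "detected": True,
    }, index=matrix.values.index.rename("mirna_id"))
    table["passes_cutoffs"] = ((table["q_value"] < q_max)
                               & (table["log2fc"].abs() > fc_min)
                               & (table["mean_expression"] > expr_min))
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    return table


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["mean_expression", "log2fc", "p_value", "q_value", "detected",
            "passes_cutoffs", "direction"]
    table[cols].to_csv(path, sep="\t", index_label="mirna_id")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="mirna_id")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def pca(matrix: ExpressionMatrix, k: int = 2) -> PCAResult:
    """PCA of samples in miRNA space (rows mean-centered as features)."""
    X = matrix.values.T.values  # samples x features
    if k > min(X.shape):
        raise InputError(f"k={k} exceeds matrix rank bound {min(X.shape)}")
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=model.explained_variance_ratio_,
    )
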