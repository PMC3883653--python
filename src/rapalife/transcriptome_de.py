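"""Expression normalization, per-probe differential testing and overlap summaries.

The workflow mirrors a classic two-color-free microarray analysis: log2
transform, quantile normalization (every sample forced onto the common
distribution of row-wise means of sorted columns), per-probe two-sample
t-tests with Benjamini–Hochberg false-discovery-rate control, and a joint
filter of adjusted p and percent change on the linear scale.  Gene lists
carry directions (up/down) so overlaps between contrasts can be counted
direction-consistently, as when comparing the responder-male response to the
female response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Probes × samples intensities plus sample metadata.

    ``log2_scale`` records whether values are already log2; linear-scale
    intensities must be strictly positive.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    log2_scale: bool = False
    detection: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing intensities")
        if not self.log2_scale:
            bad = self.values <= 0
            if bad.any().any():
                probe = bad.any(axis=1).idxmax()
                sample = bad.loc[probe].idxmax()
                raise ValueError(
                    f"non-positive linear intensity at probe {probe!r}, sample {sample!r}")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")

    def samples_in_group(self, group: str) -> list[str]:
        return self.metadata.index[self.metadata["group"] == group].tolist()


@dataclass
class DEFilter:
    """Joint significance/effect-size filter with strict inequalities.

    Exactly one change-threshold mode is active: ``min_percent_change``
    (linear scale, |2^Δ − 1|·100 > threshold) or ``min_abs_log2fc``.
    """

    adjusted_p_max: float = 0.05
    min_percent_change: float | None = 15.0
    min_abs_log2fc: float | None = None
    use_raw_p: bool = False

    def __post_init__(self):
        if (self.min_percent_change is None) == (self.min_abs_log2fc is None):
            raise ValueError("exactly one of min_percent_change / min_abs_log2fc must be set")


@dataclass
class OverlapSummary:
    up_shared: int
    down_shared: int
    total_shared: int
    n_up_a: int
    n_down_a: int
    n_a: int
    n_b: int
    pct_up: float
    pct_down: float
    pct_total: float


def _quantile_normalize_log2(log2_df: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization: assign row means of sorted columns by rank.

    Ties within a column receive the mean of the reference values at their
    tied rank positions, so the operation is deterministic and idempotent.
    """
    arr = log2_df.to_numpy(float)
    ref = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty_like(ref)
        ranked[order] = ref
        # average reference values over tied blocks
        sorted_col = col[order]
        start = 0
        for i in range(1, len(col) + 1):
            if i == len(col) or sorted_col[i] != sorted_col[start]:
                if i - start > 1:
                    ranked[order[start:i]] = ref[start:i].mean()
                start = i
        out[:, j] = ranked
    return pd.DataFrame(out, index=log2_df.index, columns=log2_df.columns)


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 transform (if needed) followed by quantile normalization.

    After normalization every column shares an identical multiset of values;
    applying the operation twice equals applying it once.
    """
    log2_df = matrix.values if matrix.log2_scale else np.log2(matrix.values)
    qn = _quantile_normalize_log2(log2_df)
    return ExpressionMatrix(values=qn, metadata=matrix.metadata, log2_scale=True,
                            detection=matrix.detection)


def detected_probes(matrix: ExpressionMatrix, min_samples: int = 1) -> pd.Index:
    """Probes flagged detected in at least ``min_samples`` samples (all, if no flags)."""
    if matrix.detection is None:
        return matrix.values.index
    keep = matrix.detection.sum(axis=1) >= min_samples
    return matrix.values.index[keep]


def differential_test(matrix: ExpressionMatrix, group_a: list[str], group_b: list[str],
                      *, equal_var: bool = True) -> pd.DataFrame:
    """Per-probe two-sample t-test of group A vs group B on the log2 scale.

    Returns a table with group means, log2 fold change (A − B), percent
    change on the linear scale, t statistic, raw and B-H adjusted p, and a
    direction call (sign of the fold change for significant probes; assigned
    here for all probes, thresholding happens in ``filter_de``).  Probes with
    zero pooled variance get p = 1 and are flagged ``constant``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 samples per group")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not matrix.log2_scale:
        raise ValueError("run normalize() first: differential testing expects log2 values")

    A = matrix.values[group_a].to_numpy(float)
    B = matrix.values[group_b].to_numpy(float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    constant = ~np.isfinite(t)
    t = np.where(constant, 0.0, t)
    p = np.where(constant, 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    log2fc = mean_a - mean_b
    percent = 100.0 * (np.exp2(log2fc) - 1.0)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
        "percent_change": percent, "t": t, "p": p, "adjusted_p": adj,
        "direction": direction, "constant": constant,
    }, index=matrix.values.index)


def filter_de(contrast: pd.DataFrame, flt: DEFilter) -> pd.DataFrame:
    """Apply the joint filter; both criteria are strict inequalities.

    Returns the significant rows (probe index, direction column retained).
    """
    pcol = "p" if flt.use_raw_p else "adjusted_p"
    keep = contrast[pcol] < flt.adjusted_p_max
    if flt.min_percent_change is not None:
        keep &= contrast["percent_change"].abs() > flt.min_percent_change
    else:
        keep &= contrast["log2fc"].abs() > flt.min_abs_log2fc
    out = contrast.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def overlap(list_a: pd.DataFrame, list_b: pd.DataFrame) -> OverlapSummary:
    """Direction-consistent overlap of two DE gene lists.

    Counts probes called up in both and down in both; percentages use the
    A-side denominators (genes up/down/total in list A).
    """
    up_a = set(list_a.index[list_a["direction"] == "up"])
    dn_a = set(list_a.index[list_a["direction"] == "down"])
    up_b = set(list_b.index[list_b["direction"] == "up"])
    dn_b = set(list_b.index[list_b["direction"] == "down"])
    up_shared = len(up_a & up_b)
    down_shared = len(dn_a & dn_b)
    total = up_shared + down_shared
    n_a = len(up_a) + len(dn_a)

    def pct(num, den):
        return 100.0 * num / den if den else 0.0

    return OverlapSummary(
        up_shared=up_shared, down_shared=down_shared, total_shared=total,
        n_up_a=len(up_a), n_down_a=len(dn_a), n_a=n_a, n_b=len(up_b) + len(dn_b),
        pct_up=pct(up_shared, len(up_a)), pct_down=pct(down_shared, len(dn_a)),
        pct_total=pct(total, n_a),
    )


def relative_matrix(matrix: ExpressionMatrix, reference_group: str) -> pd.DataFrame:
    """log2 expression relative to the mean of a reference group, per probe."""
    ref_samples = matrix.samples_in_group(reference_group)
    if not ref_samples:
        raise ValueError(f"reference group {reference_group!r} is empty")
    if not matrix.log2_scale:
        raise ValueError("relative_matrix expects log2 values; run normalize() first")
    ref_mean = matrix.values[ref_samples].mean(axis=1)
    return matrix.values.sub(ref_mean, axis=0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(values_path, metadata_path, *, sep: str = "\t",
                        log2_scale: bool = False) -> ExpressionMatrix:
    """Read a probes × samples table plus a sample-metadata table."""
    values = pd.read_csv(values_path, sep=sep, index_col=0)
    meta = pd.read_csv(metadata_path, sep=sep, index_col=0)
    return ExpressionMatrix(values=values, metadata=meta, log2_scale=log2_scale)


def read_series_matrix(path, metadata: pd.DataFrame, *, log2_scale: bool = False) -> ExpressionMatrix:
    """Minimal GEO series-matrix reader.

    Header lines beginning with "!" are skipped; the expression table lies
    between the matrix-begin and matrix-end markers.
    """
    lines = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if in_table:
                lines.append(line)
            elif not line.startswith("!") and line.strip():
                raise ValueError("unexpected non-header line outside the series-matrix table")
    if not lines:
        raise ValueError(f"no series-matrix table found in {path}")
    from io import StringIO
    values = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
    values.columns = [c.strip('"') for c in values.columns]
    values.index = [str(i).strip('"') for i in values.index]
    return ExpressionMatrix(values=values, metadata=metadata, log2_scale=log2_scale)


def write_gene_list(de_table: pd.DataFrame, path) -> None:
    """Two-column TSV (probe, direction)."""
    de_table[["direction"]].rename_axis("probe").to_csv(path, sep="\t")
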