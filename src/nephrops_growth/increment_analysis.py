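"""Growth-increment summaries and moult-frequency inference.

The distribution of tagging increments carries the moult signal: in a
species moulting 1-2 times per year the increment histogram is uni- or
bi-modal, and the mode an animal falls in tells how many times it moulted
while at liberty.  This module builds the per-size-class increment/weight
tables, classifies increments into moult modes, runs the standard
comparisons (one- vs two-moulter starting sizes, wild vs captive growth,
starting size vs increment), and detects moults in captive monthly series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .conversions import ConversionParams, dcl_to_dtl, dweight

logger = logging.getLogger(__name__)


def weighted_overall_mean(counts, means) -> float:
    """Count-weighted overall mean of per-class means (classes with n=0 skipped)."""
    counts = np.asarray(counts, dtype=float)
    means = np.asarray(means, dtype=float)
    mask = counts > 0
    return float(np.average(means[mask], weights=counts[mask]))


def round_display(x, decimals: int = 1):
    """Table-display rounding: half away from zero, to ``decimals`` places.

    Plain float rounding is round-half-even, which would print 4.65 as 4.6;
    published fisheries tables round half up.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def _se(values: np.ndarray) -> float:
    """Standard error of the mean; 0.0 for a single observation."""
    if values.size <= 1:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def build_size_class_table(records: pd.DataFrame, class_edges,
                           conversions: ConversionParams | None = None) -> pd.DataFrame:
    """Per-size-class increment summary (mean +/- SE of dCL, dTL, dW).

    Classes are indexed by release CL, left-closed on ``class_edges``;
    records outside all classes are logged and excluded.  The returned frame
    has one row per class plus an ``overall`` row holding the count-weighted
    means; ``attrs["n_excluded"]`` records how many fell outside.
    """
    conversions = conversions or ConversionParams()
    edges = np.asarray(class_edges, dtype=float)
    df = records.copy()
    df["dTL"] = dcl_to_dtl(df["dL"], conversions)
    df["dW"] = dweight(df["release_cl_mm"], df["recapture_cl_mm"], conversions)
    inside = (df["release_cl_mm"] >= edges[0]) & (df["release_cl_mm"] < edges[-1])
    n_excluded = int((~inside).sum())
    if n_excluded:
        logger.info("build_size_class_table: %d record(s) outside the class range excluded", n_excluded)
    df = df[inside]
    cls = pd.cut(df["release_cl_mm"], bins=edges, right=False)
    rows = []
    for interval, grp in df.groupby(cls, observed=False):
        rows.append(
            {
                "class_lower_mm": interval.left,
                "class_upper_mm": interval.right,
                "n": int(len(grp)),
                "mean_dcl_mm": grp["dL"].mean() if len(grp) else np.nan,
                "se_dcl_mm": _se(grp["dL"].to_numpy()),
                "mean_dtl_mm": grp["dTL"].mean() if len(grp) else np.nan,
                "se_dtl_mm": _se(grp["dTL"].to_numpy()),
                "mean_dw_g": grp["dW"].mean() if len(grp) else np.nan,
                "se_dw_g": _se(grp["dW"].to_numpy()),
            }
        )
    table = pd.DataFrame(rows)
    overall = {
        "class_lower_mm": np.nan, "class_upper_mm": np.nan, "n": int(len(df)),
        "mean_dcl_mm": df["dL"].mean() if len(df) else np.nan,
        "se_dcl_mm": _se(df["dL"].to_numpy()),
        "mean_dtl_mm": df["dTL"].mean() if len(df) else np.nan,
        "se_dtl_mm": _se(df["dTL"].to_numpy()),
        "mean_dw_g": df["dW"].mean() if len(df) else np.nan,
        "se_dw_g": _se(df["dW"].to_numpy()),
    }
    table = pd.concat([table, pd.DataFrame([overall], index=["overall"])])
    table.attrs["n_excluded"] = n_excluded
    return table


def increment_histogram(dcl, bin_width: float = 1.0):
    """Left-closed increment histogram from 0; returns (edges, counts)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dcl = np.asarray(dcl, dtype=float)
    if dcl.size == 0:
        edges = np.array([0.0, bin_width])
        return edges, np.zeros(1, dtype=int)
    top = bin_width * (np.floor(dcl.max() / bin_width) + 1)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(dcl, bins=edges)
    return edges, counts


def count_local_maxima(counts, min_height: int = 1) -> int:
    """Number of local maxima (>= both neighbours, strictly above one) in a histogram."""
    c = np.asarray(counts, dtype=float)
    padded = np.concatenate([[-1.0], c, [-1.0]])
    n = 0
    i = 1
    while i <= c.size:
        # treat flat-topped plateaus as a single candidate mode
        j = i
        while j + 1 <= c.size and padded[j + 1] == padded[i]:
            j += 1
        if padded[i] >= min_height and padded[i - 1] < padded[i] and padded[j + 1] < padded[i]:
            n += 1
        i = j + 1
    return n


@dataclass(frozen=True)
class MoultModeClassification:
    """Increment windows assigning a moult count to each record.

    Defaults follow the observed wild male modes: increments below 4.49 mm =
    one moult, 5.50-8.49 mm = two moults, above 8.49 mm = three or more;
    the 4.49-5.50 mm gap between the published windows is 'unclassified' and
    excluded from two-group comparisons.
    """

    mode1_upper: float = 4.49   # exclusive
    mode2_lower: float = 5.50   # inclusive
    mode2_upper: float = 8.49   # inclusive
    labels: tuple[str, ...] = ("1 moult", "2 moults", ">=3 moults", "unclassified")

    def classify(self, dcl: float) -> str:
        if dcl < self.mode1_upper:
            return self.labels[0]
        if self.mode2_lower <= dcl <= self.mode2_upper:
            return self.labels[1]
        if dcl > self.mode2_upper:
            return self.labels[2]
        return self.labels[3]


def classify_moult_modes(records: pd.DataFrame,
                         classification: MoultModeClassification | None = None):
    """Label each filtered record with its inferred moult count.

    Returns ``(labelled, counts)``: the records with a ``moult_mode`` column
    and a per-label count dict (labels partition the records exactly).
    """
    classification = classification or MoultModeClassification()
    labelled = records.copy()
    labelled["moult_mode"] = [classification.classify(d) for d in labelled["dL"]]
    counts = {lab: int((labelled["moult_mode"] == lab).sum()) for lab in classification.labels}
    return labelled, counts


def compare_mode_starting_sizes(group1_sizes, group2_sizes, equal_var: bool = True):
    """Two-sample t on release CL of one-moulters vs two-moulters.

    Positive t means group 1 (one-moulters) started larger.  ``equal_var``
    selects the pooled-variance test (df = n1+n2-2); False gives Welch.
    Returns (t, df, two-sided p).
    """
    g1 = np.asarray(group1_sizes, dtype=float)
    g2 = np.asarray(group2_sizes, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("both groups need n >= 2")
    res = stats.ttest_ind(g1, g2, equal_var=equal_var)
    if equal_var:
        dof = g1.size + g2.size - 2
    else:
        v1, v2 = g1.var(ddof=1) / g1.size, g2.var(ddof=1) / g2.size
        dof = (v1 + v2) ** 2 / (v1**2 / (g1.size - 1) + v2**2 / (g2.size - 1))
    return float(res.statistic), float(dof), float(res.pvalue)


@dataclass
class MannWhitneyResult:
    U: float
    p_value: float
    median_1: float
    range_1: tuple[float, float]
    median_2: float
    range_2: tuple[float, float]
    n_1: int
    n_2: int


def wild_vs_captive_test(wild_dcl, captive_dcl, convention: str = "min") -> MannWhitneyResult:
    """Mann-Whitney comparison of wild vs captive growth increments.

    Reports the median (range) per group and U; ``convention='min'`` reports
    the smaller of the two rank-sum-derived statistics (classic stats-package
    output), ``'first'`` the statistic of the first sample.  Ties use
    mid-ranks; p is two-sided (normal approximation with tie correction).
    """
    w = np.asarray(wild_dcl, dtype=float)
    c = np.asarray(captive_dcl, dtype=float)
    if w.size == 0 or c.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(w, c, alternative="two-sided", method="asymptotic")
    U1 = float(res.statistic)
    U = min(U1, w.size * c.size - U1) if convention == "min" else U1
    return MannWhitneyResult(
        U=U, p_value=float(res.pvalue),
        median_1=float(np.median(w)), range_1=(float(w.min()), float(w.max())),
        median_2=float(np.median(c)), range_2=(float(c.min()), float(c.max())),
        n_1=int(w.size), n_2=int(c.size),
    )


def size_growth_correlation(release_cl, dcl):
    """Spearman rank correlation (mid-rank ties) of starting size vs increment."""
    release_cl = np.asarray(release_cl, dtype=float)
    if release_cl.size < 3:
        raise ValueError("need at least 3 records")
    res = stats.spearmanr(release_cl, np.asarray(dcl, dtype=float))
    return float(res.statistic), float(res.pvalue)


def detect_captive_moults(cl_series, flags=None, threshold: float = 0.5):
    """Indices i where a moult occurred between observations i and i+1.

    A moult is a CL increase > ``threshold`` mm sustained over all later
    observations (every subsequent CL stays above CL_i + threshold), or any
    externally flagged event (shell fragments / soft shell).  Series shorter
    than 2 observations yield no events (with a warning).
    """
    cl = np.asarray(cl_series, dtype=float)
    if cl.size < 2:
        logger.warning("detect_captive_moults: series too short (%d obs)", cl.size)
        return []
    events = set()
    for i in range(cl.size - 1):
        if cl[i + 1] - cl[i] > threshold and np.all(cl[i + 1:] > cl[i] + threshold):
            events.add(i)
    if flags is not None:
        for j, flag in enumerate(np.asarray(flags, dtype=bool)):
            if flag and j > 0:
                events.add(j - 1)
    return sorted(events)
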