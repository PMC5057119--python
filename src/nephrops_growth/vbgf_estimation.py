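"""VBGF parameter estimation from catch length frequencies and tag returns.

Two estimators, deliberately decoupled because L_inf and k are strongly
inter-dependent when fitted jointly:

* Powell-Wetherall: for cutoff lengths L' over the fully recruited range,
  the mean length above the cutoff satisfies (under steady state, constant
  recruitment, exponential mortality Z and VBGF growth)
  Lbar - L' = a + b L', with L_inf = -a/b and Z/k = -(1+b)/b.
* Forced Gulland-Holt: with L_inf fixed, annualized tagging increments
  dL/dt regress through the fixed point (Lbar = L_inf, rate = 0), giving a
  one-parameter least-squares estimate of k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateFitError, EmptyTailError, InvalidParameterError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class LengthFrequencyTable:
    """Binned carapace-length counts, optionally backed by the raw lengths.

    Bins are left-closed, right-open, of constant width.  When raw lengths
    are available, tail means are computed from them (no mid-point
    approximation); a table built from pre-binned counts uses bin midpoints.
    """

    def __init__(self, lower_edges, counts, bin_width: float, raw_lengths=None,
                 sex: str | None = None, month: int | None = None):
        self.lower_edges = np.asarray(lower_edges, dtype=float)
        self.counts = np.asarray(counts, dtype=float)
        if self.lower_edges.shape != self.counts.shape:
            raise InvalidParameterError("edges and counts must have equal length")
        if bin_width <= 0:
            raise InvalidParameterError("bin width must be positive")
        if (self.counts < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        self.bin_width = float(bin_width)
        self.raw_lengths = None if raw_lengths is None else np.sort(np.asarray(raw_lengths, dtype=float))
        self.sex = sex
        self.month = month

    @classmethod
    def from_lengths(cls, lengths, bin_width: float = 2.0, origin: float = 0.0, **kw):
        """Bin raw per-individual lengths with left-closed edges anchored at ``origin``."""
        lengths = np.asarray(lengths, dtype=float)
        if lengths.size == 0:
            return cls(np.array([]), np.array([]), bin_width, raw_lengths=lengths, **kw)
        first = np.floor((lengths.min() - origin) / bin_width)
        last = np.floor((lengths.max() - origin) / bin_width)
        edges = origin + bin_width * np.arange(first, last + 2)
        counts, _ = np.histogram(lengths, bins=edges)
        return cls(edges[:-1], counts, bin_width, raw_lengths=lengths, **kw)

    @classmethod
    def from_binned(cls, lower_edges, counts, bin_width: float = 2.0, **kw):
        order = np.argsort(np.asarray(lower_edges, dtype=float))
        return cls(np.asarray(lower_edges, dtype=float)[order],
                   np.asarray(counts, dtype=float)[order], bin_width, **kw)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def midpoints(self) -> np.ndarray:
        return self.lower_edges + self.bin_width / 2.0

    def tail_count(self, L_prime: float) -> float:
        if self.raw_lengths is not None:
            return float((self.raw_lengths >= L_prime).sum())
        return float(self.counts[self.lower_edges >= L_prime].sum())

    def mean_above(self, L_prime: float) -> float:
        """Count-weighted mean length of individuals at or above ``L_prime``."""
        if self.raw_lengths is not None:
            tail = self.raw_lengths[self.raw_lengths >= L_prime]
            if tail.size == 0:
                raise EmptyTailError(f"no individuals at or above {L_prime} mm")
            return float(tail.mean())
        mask = self.lower_edges >= L_prime
        w = self.counts[mask]
        if w.sum() == 0:
            raise EmptyTailError(f"no individuals at or above {L_prime} mm")
        return float(np.average(self.midpoints[mask], weights=w))

    def scaled(self, factor: float) -> "LengthFrequencyTable":
        """Same table with all counts multiplied by ``factor`` (> 0)."""
        return LengthFrequencyTable(self.lower_edges, self.counts * factor, self.bin_width,
                                    sex=self.sex, month=self.month)


def mean_length_above_cutoff(lf: LengthFrequencyTable, L_prime: float) -> float:
    """Mean length of the sample at or above the cutoff ``L_prime`` (mm)."""
    return lf.mean_above(L_prime)


@dataclass
class PowellWetherallFit:
    """OLS of (Lbar - L') on L' over fully recruited cutoffs."""

    cutoffs: np.ndarray
    mean_above: np.ndarray
    a: float          # intercept, mm
    b: float          # slope, dimensionless; valid fits have b in (-1, 0)
    L_inf_hat: float  # -a/b, mm
    Z_over_k_hat: float  # -(1+b)/b
    n_points: int
    r_squared: float
    se_a: float = float("nan")
    se_b: float = float("nan")

    def summary(self) -> str:
        return (
            f"Powell-Wetherall: n_points={self.n_points}, a={self.a:.4f} mm, "
            f"b={self.b:.5f}, L_inf={self.L_inf_hat:.2f} mm, "
            f"Z/k={self.Z_over_k_hat:.3f}, r^2={self.r_squared:.4f}"
        )


@dataclass
class GullandHoltFit:
    """Forced one-parameter Gulland-Holt regression through (L_inf, 0)."""

    L_inf_fixed: float
    k_hat: float           # yr^-1
    n_records: int
    residual_sd: float     # mm yr^-1
    n_excluded: int = 0    # records with Lbar >= L_inf, dropped with warning


@dataclass
class PooledGullandHoltFit:
    pooled: GullandHoltFit
    per_year: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# increment records


def increments_from_records(records: pd.DataFrame) -> pd.DataFrame:
    """Derive dL, Lbar, dt (days) and annualized rate from tag records.

    Accepts either ISO release/recapture dates or a precomputed
    ``liberty_days`` column.
    """
    df = records.copy()
    if "liberty_days" not in df.columns:
        rel = pd.to_datetime(df["release_date"])
        rec = pd.to_datetime(df["recapture_date"])
        df["liberty_days"] = (rec - rel).dt.days.astype(float)
    df["dL"] = df["recapture_cl_mm"] - df["release_cl_mm"]
    df["Lbar"] = (df["recapture_cl_mm"] + df["release_cl_mm"]) / 2.0
    df["rate"] = df["dL"] / (df["liberty_days"] / DAYS_PER_YEAR)
    return df


def filter_increments(records: pd.DataFrame, min_dL: float = 0.0):
    """Apply the standard tag-return exclusions, keeping an audit trail.

    Drops records with zero/negative growth (dL <= ``min_dL``), unreadable
    tags (missing tag id) or missing lengths/dates; returns
    ``(kept, dropped)`` where ``dropped`` carries a per-record ``reason``.
    """
    df = increments_from_records(records) if "dL" not in records.columns else records.copy()
    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    unreadable = df["tag_id"].isna() if "tag_id" in df.columns else pd.Series(False, index=df.index)
    missing = df[["release_cl_mm", "recapture_cl_mm"]].isna().any(axis=1) | df["liberty_days"].isna()
    nonpos_dt = df["liberty_days"] <= 0
    nonpos_growth = df["dL"] <= min_dL
    reason[nonpos_growth] = "non-positive growth"
    reason[nonpos_dt] = "non-positive liberty"
    reason[missing] = "missing field"
    reason[unreadable] = "unreadable tag"
    dropped = df[reason.notna()].assign(reason=reason[reason.notna()])
    kept = df[reason.isna()]
    for r, n in dropped["reason"].value_counts().items():
        logger.info("filter_increments: dropped %d record(s): %s", n, r)
    return kept, dropped


def drop_counts(dropped: pd.DataFrame) -> dict:
    """Audit counts per drop reason."""
    if len(dropped) == 0:
        return {}
    return dropped["reason"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# Powell-Wetherall


def wetherall_points(lf: LengthFrequencyTable, recruit_length: float,
                     min_tail_count: float = 5.0):
    """(cutoffs, tail means) at bin lower edges from the recruitment length up.

    Cutoffs stop at the last bin whose tail still holds ``min_tail_count``
    individuals, restricting the regression to well-estimated points.
    """
    cutoffs, means = [], []
    for edge in lf.lower_edges:
        if edge < recruit_length:
            continue
        if lf.tail_count(edge) < min_tail_count:
            break
        cutoffs.append(float(edge))
        means.append(lf.mean_above(edge))
    return np.asarray(cutoffs), np.asarray(means)


def wetherall_regression(cutoffs, mean_above) -> PowellWetherallFit:
    """OLS of y = Lbar - L' on L'; L_inf = -a/b, Z/k = -(1+b)/b."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    mean_above = np.asarray(mean_above, dtype=float)
    if cutoffs.size < 3:
        raise DegenerateFitError(f"need >= 3 cutoff points, got {cutoffs.size}")
    if np.unique(cutoffs).size < 2:
        raise DegenerateFitError("cutoff points are collinear (identical L' values)")
    y = mean_above - cutoffs
    model = sm.OLS(y, sm.add_constant(cutoffs)).fit()
    a, b = float(model.params[0]), float(model.params[1])
    if not -1.0 < b < 0.0:
        raise DegenerateFitError(
            f"slope b={b:.4f} outside (-1, 0); the sample violates the "
            "steady-state assumptions (no valid L_inf estimate)"
        )
    return PowellWetherallFit(
        cutoffs=cutoffs, mean_above=mean_above, a=a, b=b,
        L_inf_hat=-a / b, Z_over_k_hat=-(1.0 + b) / b,
        n_points=int(cutoffs.size), r_squared=float(model.rsquared),
        se_a=float(model.bse[0]), se_b=float(model.bse[1]),
    )


def powell_wetherall(lf: LengthFrequencyTable, recruit_length: float,
                     min_tail_count: float = 5.0) -> PowellWetherallFit:
    """Estimate L_inf (and Z/k) from a catch length-frequency sample.

    ``recruit_length`` is the smallest length fully retained by the fishery;
    only cutoffs at or above it enter the regression.
    """
    cutoffs, means = wetherall_points(lf, recruit_length, min_tail_count)
    return wetherall_regression(cutoffs, means)


# ---------------------------------------------------------------------------
# forced Gulland-Holt


def forced_gulland_holt(records: pd.DataFrame, L_inf: float) -> GullandHoltFit:
    """Estimate k with L_inf fixed, from filtered increment records.

    Least squares of rate_i on x_i = L_inf - Lbar_i through the origin:
    k = sum(rate x) / sum(x^2).  Records with Lbar >= L_inf cannot inform a
    VBGF slope and are excluded with a warning.
    """
    df = records if "rate" in records.columns else increments_from_records(records)
    valid = df["Lbar"] < L_inf
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("forced_gulland_holt: excluded %d record(s) with Lbar >= L_inf", n_excluded)
    df = df[valid]
    if len(df) == 0:
        raise DegenerateFitError("no usable records (all Lbar >= L_inf)")
    x = (L_inf - df["Lbar"]).to_numpy(dtype=float)
    r = df["rate"].to_numpy(dtype=float)
    k_hat = float(np.dot(r, x) / np.dot(x, x))
    resid = r - k_hat * x
    residual_sd = float(np.sqrt(np.mean(resid**2))) if len(df) > 1 else 0.0
    return GullandHoltFit(L_inf_fixed=float(L_inf), k_hat=k_hat,
                          n_records=int(len(df)), residual_sd=residual_sd,
                          n_excluded=n_excluded)


def pool_and_estimate(year1_records: pd.DataFrame, year2_records: pd.DataFrame | None,
                      L_inf: float) -> PooledGullandHoltFit:
    """Pool liberty periods into a single forced fit, keeping per-year fits.

    Pooling concatenates the filtered records and fits once; the pooled k is
    an x^2-weighted average of the per-year estimates.
    """
    years = [y for y in (year1_records, year2_records) if y is not None and len(y) > 0]
    if not years:
        raise DegenerateFitError("no records to pool")
    per_year = [forced_gulland_holt(y, L_inf) for y in years]
    pooled = forced_gulland_holt(pd.concat(years, ignore_index=True), L_inf)
    return PooledGullandHoltFit(pooled=pooled, per_year=per_year)
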