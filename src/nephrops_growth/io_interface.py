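"""CSV/YAML input-output and the end-to-end analysis pipeline.

All tabular interchange is CSV with ISO-8601 dates; lengths are mm CL,
weights grams.  Malformed rows are collected into an error frame with a
per-row reason, never silently dropped, mirroring the explicit accounting
of excluded records in field studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import vbgf_estimation as vbgf
from .conversions import ConversionParams
from .exceptions import DegenerateFitError, SchemaError
from .growth_sim import SimConfig, simulate_catch_lengths, simulate_tag_recapture
from .increment_analysis import (
    MoultModeClassification,
    build_size_class_table,
    classify_moult_modes,
    compare_mode_starting_sizes,
    size_growth_correlation,
)
from .vbgf_estimation import LengthFrequencyTable

logger = logging.getLogger(__name__)

TAG_COLUMNS = ["tag_id", "sex", "release_date", "release_cl_mm", "recapture_date", "recapture_cl_mm"]
CAPTIVE_COLUMNS = ["tag_id", "sex", "obs_date", "cl_mm"]

#: liberty-period boundary (days) separating ~1-year from ~2-year returns
YEAR_SPLIT_DAYS = 500.0


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_tag_records(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read tag-recapture records; returns (records, rejected_rows).

    Dates are parsed as ISO-8601 and liberty computed in days; rows with
    unparseable dates or a recapture before release are moved to the error
    frame with a reason.
    """
    df = pd.read_csv(path)
    _require_columns(df, TAG_COLUMNS, path)
    rel = pd.to_datetime(df["release_date"], format="%Y-%m-%d", errors="coerce")
    rec = pd.to_datetime(df["recapture_date"], format="%Y-%m-%d", errors="coerce")
    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    reason[(rec - rel).dt.days <= 0] = "recapture not after release"
    reason[rel.isna() | rec.isna()] = "unparseable date"
    reason[~df["sex"].isin(["M", "F"])] = "invalid sex"
    df = df.assign(liberty_days=(rec - rel).dt.days.astype(float))
    errors = df[reason.notna()].assign(reason=reason[reason.notna()])
    records = df[reason.isna()].reset_index(drop=True)
    for r, n in errors.get("reason", pd.Series(dtype=object)).value_counts().items():
        logger.warning("read_tag_records: rejected %d row(s): %s", n, r)
    return records, errors


def write_tag_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=[c for c in TAG_COLUMNS if c in records.columns])


def read_length_frequency(path, bin_width: float = 2.0) -> dict[str, LengthFrequencyTable]:
    """Read a length-frequency CSV into per-sex tables (months pooled).

    Accepts raw per-individual lengths (columns sex, cl_mm [, month]) or
    pre-binned counts (sex, cl_bin_lower_mm, count [, month]).
    """
    df = pd.read_csv(path)
    if "cl_mm" in df.columns:
        _require_columns(df, ["sex", "cl_mm"], path)
        return {
            sex: LengthFrequencyTable.from_lengths(grp["cl_mm"].to_numpy(), bin_width, sex=sex)
            for sex, grp in df.groupby("sex")
        }
    _require_columns(df, ["sex", "cl_bin_lower_mm", "count"], path)
    out = {}
    for sex, grp in df.groupby("sex"):
        agg = grp.groupby("cl_bin_lower_mm", as_index=False)["count"].sum()
        out[sex] = LengthFrequencyTable.from_binned(
            agg["cl_bin_lower_mm"].to_numpy(), agg["count"].to_numpy(), bin_width, sex=sex
        )
    return out


def write_length_frequency(lengths_by_sex: dict, path, bin_width: float = 2.0,
                           month: int | None = None) -> None:
    """Bin raw lengths and write sex, month, cl_bin_lower_mm, count rows."""
    rows = []
    for sex, lengths in sorted(lengths_by_sex.items()):
        lf = LengthFrequencyTable.from_lengths(np.asarray(lengths), bin_width, sex=sex)
        for lo, c in zip(lf.lower_edges, lf.counts):
            rows.append({"sex": sex, "month": month if month is not None else "",
                         "cl_bin_lower_mm": lo, "count": int(c)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_captive_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CAPTIVE_COLUMNS, path)
    df["obs_date"] = pd.to_datetime(df["obs_date"], format="%Y-%m-%d")
    if "moult_flag" not in df.columns:
        df["moult_flag"] = False
    return df.sort_values(["tag_id", "obs_date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Everything one analysis run needs; all randomness flows from ``seed``."""

    tags_path: str | None = None
    lf_path: str | None = None
    captive_path: str | None = None
    sim: SimConfig | None = None
    n_tags: int = 2000
    n_catch: int = 20000
    recruit_length: float = 38.0
    bin_width: float = 2.0
    min_tail_count: float = 5.0
    size_class_edges: tuple[float, ...] = tuple(np.arange(26.0, 42.0, 2.0))
    conversions: ConversionParams = field(default_factory=ConversionParams)
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.recruit_length <= 0:
            raise SchemaError("recruit_length must be positive")
        if self.tags_path is None and self.sim is None:
            raise SchemaError("either tags_path or a sim config is required")


def load_run_config(path) -> RunConfig:
    """Load a flat key-value YAML config; ``sim`` keys live under 'sim'."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("sim", None)
    if sim is not None:
        if "seed" not in sim:
            raise SchemaError("sim config requires an explicit seed")
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
    conv = raw.pop("conversions", None)
    kwargs = dict(raw)
    if sim is not None:
        kwargs["sim"] = sim
    if conv is not None:
        kwargs["conversions"] = ConversionParams(**conv)
    return RunConfig(**kwargs)


def _fit_report(fit: vbgf.PowellWetherallFit) -> dict:
    return {
        "a_mm": fit.a, "b": fit.b, "L_inf_hat_mm": fit.L_inf_hat,
        "Z_over_k_hat": fit.Z_over_k_hat, "n_points": fit.n_points,
        "r_squared": fit.r_squared,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis: filter -> tables -> modes -> P-W -> forced G-H.

    Deterministic given the config (simulation seeded from ``config.seed``);
    when ``out_dir`` is set, writes the simulated/copied inputs, per-sex
    size-class tables, and a machine-readable report.json.
    """
    rng = np.random.default_rng(config.seed)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        records = simulate_tag_recapture(sim, config.n_tags, np.random.default_rng(config.seed))
        lf_by_sex = {
            sex: LengthFrequencyTable.from_lengths(
                simulate_catch_lengths(sim, config.n_catch, sex, rng), config.bin_width, sex=sex)
            for sex in ("M", "F")
        }
        if out:
            write_tag_records(records, out / "tag_records.csv")
            write_length_frequency(
                {sex: lf.raw_lengths for sex, lf in lf_by_sex.items()},
                out / "length_frequency.csv", config.bin_width)
        records = vbgf.increments_from_records(records)
        read_errors = pd.DataFrame()
    else:
        records, read_errors = read_tag_records(config.tags_path)
        records = vbgf.increments_from_records(records)
        lf_by_sex = read_length_frequency(config.lf_path, config.bin_width) if config.lf_path else {}

    kept, dropped = vbgf.filter_increments(records)
    report: dict = {
        "seed": config.seed,
        "n_records": int(len(records)),
        "n_kept": int(len(kept)),
        "drop_audit": vbgf.drop_counts(dropped),
        "n_rejected_rows": int(len(read_errors)),
        "by_sex": {},
    }

    for sex in ("M", "F"):
        sex_kept = kept[kept["sex"] == sex]
        entry: dict = {"n_kept": int(len(sex_kept))}
        year1 = sex_kept[sex_kept["liberty_days"] < YEAR_SPLIT_DAYS]
        year2 = sex_kept[sex_kept["liberty_days"] >= YEAR_SPLIT_DAYS]

        if len(sex_kept):
            table = build_size_class_table(sex_kept, config.size_class_edges, config.conversions)
            if out:
                table.to_csv(out / f"size_class_table_{sex}.csv", index=False)
            entry["overall_mean_dcl_mm"] = float(table.loc["overall", "mean_dcl_mm"])
            labelled, mode_counts = classify_moult_modes(sex_kept)
            entry["moult_mode_counts"] = mode_counts
            if len(sex_kept) >= 3:
                rho, p = size_growth_correlation(sex_kept["release_cl_mm"], sex_kept["dL"])
                entry["spearman_rho"], entry["spearman_p"] = rho, p
            g1 = labelled.loc[labelled["moult_mode"] == "1 moult", "release_cl_mm"]
            g2 = labelled.loc[labelled["moult_mode"] == "2 moults", "release_cl_mm"]
            if len(g1) >= 2 and len(g2) >= 2:
                t, dof, p = compare_mode_starting_sizes(g1, g2)
                entry["mode_size_t"], entry["mode_size_df"], entry["mode_size_p"] = t, dof, p

        lf = lf_by_sex.get(sex)
        if lf is not None:
            try:
                pw = vbgf.powell_wetherall(lf, config.recruit_length, config.min_tail_count)
                entry["powell_wetherall"] = _fit_report(pw)
                gh = vbgf.pool_and_estimate(year1 if len(year1) else None,
                                            year2 if len(year2) else None, pw.L_inf_hat)
                entry["k_hat_pooled"] = gh.pooled.k_hat
                entry["k_hat_per_year"] = [f.k_hat for f in gh.per_year]
                entry["n_gulland_holt"] = gh.pooled.n_records
            except DegenerateFitError as exc:
                entry["estimation_error"] = str(exc)
        report["by_sex"][sex] = entry

    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        with open(out / "report.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Plain-text rendering of the machine-readable report."""
    lines = [
        "Nephrops growth estimation report",
        f"seed: {report['seed']}",
        f"records: {report['n_records']} (kept {report['n_kept']})",
        f"dropped: {report['drop_audit']}",
    ]
    for sex, entry in report["by_sex"].items():
        lines.append(f"-- sex {sex} (n={entry['n_kept']})")
        pw = entry.get("powell_wetherall")
        if pw:
            lines.append(
                f"   Powell-Wetherall: L_inf = {pw['L_inf_hat_mm']:.2f} mm "
                f"(a={pw['a_mm']:.3f}, b={pw['b']:.4f}, Z/k={pw['Z_over_k_hat']:.2f}, "
                f"r^2={pw['r_squared']:.4f}, {pw['n_points']} points)"
            )
        if "k_hat_pooled" in entry:
            lines.append(f"   forced Gulland-Holt: k = {entry['k_hat_pooled']:.4f} yr^-1 "
                         f"(n={entry['n_gulland_holt']})")
        if "overall_mean_dcl_mm" in entry:
            lines.append(f"   overall mean increment: {entry['overall_mean_dcl_mm']:.2f} mm CL")
        if "moult_mode_counts" in entry:
            lines.append(f"   moult modes: {entry['moult_mode_counts']}")
    return "\n".join(lines) + "\n"
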