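"""Estimator tests: filtering, Powell-Wetherall, forced Gulland-Holt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nephrops_growth as ng
from nephrops_growth.vbgf_estimation import (
    LengthFrequencyTable,
    drop_counts,
    filter_increments,
    increments_from_records,
)


def beverton_holt_mean(L_prime, L_inf, Z_over_k):
    """Mean length above a cutoff under steady state: (Z L' + k L_inf)/(Z + k)."""
    return (Z_over_k * L_prime + L_inf) / (Z_over_k + 1.0)


def make_increment_frame(L1, L2, dt_days, sex="M", tag_ids=None):
    n = len(L1)
    df = pd.DataFrame(
        {
            "tag_id": tag_ids if tag_ids is not None else [f"T{i}" for i in range(n)],
            "sex": sex,
            "release_cl_mm": L1,
            "recapture_cl_mm": L2,
            "liberty_days": dt_days,
        }
    )
    return increments_from_records(df)


def exact_beverton_holt_sample(L_inf=70.8, Z_over_k=2.0, edges=None, bin_width=2.0):
    """Raw lengths whose tail mean above EVERY bin edge is exactly Beverton-Holt.

    Built top-down: in each bin place c identical lengths positioned so the
    running tail mean hits the closed form; c grows until the position falls
    inside the bin.  Serves as a noise-free sample generated from the
    steady-state relation itself.
    """
    edges = np.arange(38.0, 70.0, bin_width) if edges is None else np.asarray(edges)
    lengths = []
    total, count = 0.0, 0
    for edge in edges[::-1]:
        target = beverton_holt_mean(edge, L_inf, Z_over_k)
        for c in range(1, 200):
            pos = (target * (count + c) - total) / c
            if edge <= pos < edge + bin_width:
                lengths.extend([pos] * c)
                total += pos * c
                count += c
                break
        else:  # pragma: no cover - construction failure
            raise AssertionError(f"could not place points in bin at {edge}")
    return np.sort(lengths)


class TestFilterIncrements:
    def test_study_style_accounting(self):
        # 207 returns: 199 grew, 7 zero/negative growth, 1 unreadable tag
        L1 = np.full(207, 32.0)
        L2 = np.concatenate([np.full(199, 35.0), np.full(7, 32.0), [35.0]])
        tags = [f"T{i}" for i in range(206)] + [None]
        df = make_increment_frame(L1, L2, np.full(207, 344.0), tag_ids=tags)
        kept, dropped = filter_increments(df)
        assert len(kept) == 199
        audit = drop_counts(dropped)
        assert audit["non-positive growth"] == 7
        assert audit["unreadable tag"] == 1

    def test_all_positive_untouched(self):
        df = make_increment_frame([30.0, 31.0], [33.0, 35.0], [300.0, 300.0])
        kept, dropped = filter_increments(df)
        assert len(kept) == 2 and len(dropped) == 0

    def test_zero_growth_reason(self):
        df = make_increment_frame([30.0], [30.0], [300.0])
        kept, dropped = filter_increments(df)
        assert len(kept) == 0
        assert dropped["reason"].iloc[0] == "non-positive growth"

    def test_derived_columns(self):
        df = make_increment_frame([30.0], [33.0], [365.25])
        assert df["dL"].iloc[0] == pytest.approx(3.0)
        assert df["Lbar"].iloc[0] == pytest.approx(31.5)
        assert df["rate"].iloc[0] == pytest.approx(3.0)  # mm per year


class TestMeanLengthAboveCutoff:
    def test_point_mass(self):
        lf = LengthFrequencyTable.from_lengths([50.0] * 10, 2.0)
        assert ng.mean_length_above_cutoff(lf, 40.0) == 50.0

    def test_uniform_symmetry(self):
        lf = LengthFrequencyTable.from_lengths(np.linspace(38.0, 70.8, 2001), 2.0)
        assert ng.mean_length_above_cutoff(lf, 38.0) == pytest.approx(54.4, abs=1e-9)

    def test_beverton_holt_closed_form(self, rng):
        draws = ng.sample_steady_state_lengths(70.8, 2.0, 38.0, 400000, rng)
        lf = LengthFrequencyTable.from_lengths(draws, 2.0)
        # (Z L' + k L_inf)/(Z + k) = (2*38 + 70.8)/3 = 48.933
        assert ng.mean_length_above_cutoff(lf, 38.0) == pytest.approx(48.933, abs=0.05)

    def test_empty_tail(self):
        lf = LengthFrequencyTable.from_lengths([30.0, 31.0], 2.0)
        with pytest.raises(ng.EmptyTailError):
            ng.mean_length_above_cutoff(lf, 40.0)


class TestPowellWetherall:
    def test_exact_recovery_from_beverton_holt_relation(self):
        lengths = exact_beverton_holt_sample(L_inf=70.8, Z_over_k=2.0)
        lf = LengthFrequencyTable.from_lengths(lengths, 2.0, origin=0.0)
        fit = ng.powell_wetherall(lf, recruit_length=38.0, min_tail_count=1)
        assert fit.a == pytest.approx(70.8 / 3, rel=1e-9)
        assert fit.b == pytest.approx(-1.0 / 3.0, rel=1e-9)
        assert fit.L_inf_hat == pytest.approx(70.8, rel=1e-9)
        assert fit.Z_over_k_hat == pytest.approx(2.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_analytic_points_regression(self):
        cutoffs = np.arange(38.0, 66.0, 2.0)
        means = beverton_holt_mean(cutoffs, 70.8, 2.0)
        fit = ng.wetherall_regression(cutoffs, means)
        assert fit.L_inf_hat == pytest.approx(70.8, rel=1e-9)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ng.DegenerateFitError):
            ng.wetherall_regression([40.0, 42.0], [50.0, 51.0])
        with pytest.raises(ng.DegenerateFitError):
            ng.wetherall_regression([40.0, 40.0, 40.0], [50.0, 50.0, 50.0])

    def test_positive_slope_rejected(self):
        cutoffs = np.array([40.0, 44.0, 48.0, 52.0])
        means = cutoffs + np.array([1.0, 2.0, 3.0, 4.0])  # widening tail: b > 0
        with pytest.raises(ng.DegenerateFitError):
            ng.wetherall_regression(cutoffs, means)

    def test_large_sample_recovery(self, rng):
        # female envelope used as generative truth
        draws = ng.sample_steady_state_lengths(55.2, 2.0, 38.0, 100000, rng)
        lf = LengthFrequencyTable.from_lengths(draws, 2.0)
        fit = ng.powell_wetherall(lf, 38.0)
        assert fit.L_inf_hat == pytest.approx(55.2, abs=1.0)

    def test_invariant_to_count_scaling(self):
        lengths = exact_beverton_holt_sample(L_inf=55.2, Z_over_k=2.0,
                                             edges=np.arange(38.0, 54.0, 2.0))
        lf = LengthFrequencyTable.from_lengths(lengths, 2.0)
        binned = LengthFrequencyTable.from_binned(lf.lower_edges, lf.counts, 2.0)
        fit1 = ng.powell_wetherall(binned, 38.0, min_tail_count=1)
        fit2 = ng.powell_wetherall(binned.scaled(7.3), 38.0, min_tail_count=7.3)
        assert fit1.L_inf_hat == pytest.approx(fit2.L_inf_hat, rel=1e-12)
        assert fit1.b == pytest.approx(fit2.b, rel=1e-12)


class TestForcedGullandHolt:
    def test_single_record(self):
        df = make_increment_frame([48.0], [52.0], [2 * 365.25])
        # Lbar = 50, rate = 2 mm/yr, L_inf 70 -> k = 2/20
        fit = ng.forced_gulland_holt(df, 70.0)
        assert fit.k_hat == pytest.approx(0.1, abs=1e-12)

    def test_exact_recovery_on_noise_free_rates(self):
        rng = np.random.default_rng(1)
        Lbar = rng.uniform(30.0, 60.0, size=50)
        rates = 0.161 * (70.8 - Lbar)
        # build records with those exact Lbar/rate pairs over one year
        L1 = Lbar - rates / 2.0
        L2 = Lbar + rates / 2.0
        df = make_increment_frame(L1, L2, np.full(50, 365.25))
        fit = ng.forced_gulland_holt(df, 70.8)
        assert fit.k_hat == pytest.approx(0.161, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_recovery_from_simulated_females(self):
        rec = increments_from_records(ng.simulate_tag_recapture(ng.SimConfig(seed=6), 2000))
        kept, _ = filter_increments(rec)
        fit = ng.forced_gulland_holt(kept[kept.sex == "F"], 55.2)
        assert fit.k_hat == pytest.approx(0.077, rel=0.10)

    def test_excludes_records_beyond_linf(self):
        df = make_increment_frame([48.0, 70.0], [52.0, 74.0], [2 * 365.25] * 2)
        fit = ng.forced_gulland_holt(df, 70.0)
        assert fit.n_excluded == 1 and fit.n_records == 1
        assert fit.k_hat == pytest.approx(0.1, abs=1e-12)

    def test_all_beyond_linf_is_error(self):
        df = make_increment_frame([70.0], [74.0], [365.25])
        with pytest.raises(ng.DegenerateFitError):
            ng.forced_gulland_holt(df, 70.0)

    def test_linearity_in_rates(self):
        df = make_increment_frame([30.0, 35.0, 40.0], [34.0, 38.0, 43.0], [365.25] * 3)
        k_full = ng.forced_gulland_holt(df, 70.8).k_hat
        halved = df.copy()
        halved["rate"] = halved["rate"] / 2.0
        assert ng.forced_gulland_holt(halved, 70.8).k_hat == pytest.approx(k_full / 2, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_least_squares(self, seed):
        # independent oracle: grid search + exact parabola refinement of the
        # quadratic SSE (see brute_force_forced_slope in test_acceptance)
        from test_acceptance import brute_force_forced_slope

        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        Lbar = rng.uniform(25.0, 69.0, size=n)
        rate = rng.normal(2.0, 1.5, size=n)
        df = pd.DataFrame({"Lbar": Lbar, "rate": rate})
        fit = ng.forced_gulland_holt(df, 70.8)
        oracle = brute_force_forced_slope(70.8 - Lbar, rate)
        assert fit.k_hat == pytest.approx(oracle, abs=1e-9)


class TestPooling:
    def _records(self, seed, n=40):
        rng = np.random.default_rng(seed)
        L1 = rng.uniform(28.0, 45.0, size=n)
        dL = rng.uniform(0.5, 8.0, size=n)
        return make_increment_frame(L1, L1 + dL, rng.uniform(300.0, 700.0, size=n))

    def test_pooling_identical_sets_is_idempotent(self):
        y1 = self._records(0)
        fit = ng.pool_and_estimate(y1, y1.copy(), 70.8)
        assert fit.pooled.k_hat == pytest.approx(ng.forced_gulland_holt(y1, 70.8).k_hat, rel=1e-12)

    def test_single_year_passthrough(self):
        y1 = self._records(1)
        fit = ng.pool_and_estimate(y1, None, 70.8)
        assert fit.pooled.k_hat == ng.forced_gulland_holt(y1, 70.8).k_hat
        assert len(fit.per_year) == 1

    def test_pooled_between_per_year_estimates(self):
        y1, y2 = self._records(2), self._records(3)
        fit = ng.pool_and_estimate(y1, y2, 70.8)
        ks = sorted(f.k_hat for f in fit.per_year)
        assert ks[0] <= fit.pooled.k_hat <= ks[1]
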