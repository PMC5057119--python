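"""Individual-based synthetic population for Nephrops norvegicus growth studies.

Growth in clawed lobsters is episodic: carapace length (CL) is constant
between moults and jumps at ecdysis.  Averaged over a cohort the steps trace
a von Bertalanffy growth function (VBGF) envelope

    L(t) = L_inf - (L_inf - L0) * exp(-k t),

so a tag-recapture estimator that assumes smooth VBGF growth can still be
consistent provided the per-moult jumps release, on average, one year of
envelope growth per year.  This module generates three kinds of synthetic
data with exactly that structure:

* tag-recapture records (release/recapture CL and dates),
* captive monthly CL time series with moult flags,
* steady-state catch length frequencies under constant recruitment and
  exponential mortality (the population the Powell-Wetherall plot assumes).

Moulting design.  Females moult once per year; males moult once plus a
second time with a size-dependent probability p(CL) = clamp(a + b*CL, 0, 1),
b < 0, so smaller males moult more often.  Each moult advances the animal
along its sex's VBGF envelope by a fixed "envelope time" tau: tau = 1 yr for
females, tau = 1/(1 + p_bar) yr for males (p_bar = mean second-moult
probability over the release-size range).  Hence the population-mean growth
rate tracks the envelope exactly, while one- and two-moult males separate
into the two increment modes seen in wild data.  Calendar moult timing is
seasonal (monthly multinomial weights); an animal's cycle phase is anchored
to its own last moult, which may pre-date release, so animals recaptured
before their next moult contribute the zero-growth class.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

DAYS_PER_YEAR = 365.25

#: first day-of-year (0-based) of each month in a 365-day reference year
_MONTH_STARTS = np.cumsum([0] + [calendar.monthrange(2013, m)[1] for m in range(1, 13)])

# Wild seasonal defaults: females moult mainly April-May (post-spawning);
# wild male moulting is spread over an extended spring-autumn period.
_FEMALE_WILD_WEIGHTS = (0.0, 0.0, 0.5, 4.0, 4.0, 0.5, 0.25, 0.25, 0.25, 0.25, 0.0, 0.0)
_MALE_WILD_WEIGHTS = (0.25, 0.25, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.25, 0.25)

# Captive timing (holding-tank observations): male peak Nov-Dec, female Apr-May.
_MALE_CAPTIVE_WEIGHTS = (0.5, 0.5, 0.25, 0.5, 0.5, 0.0, 0.5, 0.5, 0.5, 0.5, 4.0, 4.0)
_FEMALE_CAPTIVE_WEIGHTS = (0.25, 0.25, 0.25, 4.0, 4.0, 0.0, 0.5, 0.5, 0.5, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic population and sampling design.

    Lengths are mm carapace length (CL), rates yr^-1, durations days.
    Defaults correspond to a lightly exploited west-of-Ireland population:
    male envelope (70.8 mm, 0.161 yr^-1), female envelope (55.2 mm,
    0.077 yr^-1), release sizes 26.9-40.2 mm (M) / 22.0-44.6 mm (F),
    mid-June releases recaptured after ~344 +/- 34 days.
    """

    L_inf_m: float = 70.8
    k_m: float = 0.161
    L_inf_f: float = 55.2
    k_f: float = 0.077
    #: total mortality / growth-constant ratio of the catch population
    Z_over_k: float = 2.0
    #: smallest length retained by the fishery (mm CL)
    L_c: float = 25.0
    release_size_range_m: tuple[float, float] = (26.9, 40.2)
    release_size_range_f: tuple[float, float] = (22.0, 44.6)
    #: male second-moult probability p(CL) = clamp(intercept + slope*CL, 0, 1)
    p_second_moult_intercept: float = 2.18
    p_second_moult_slope: float = -0.05
    #: probability of a rare third male moult (off by default)
    p_third_moult: float = 0.0
    moult_season_weights_m: tuple[float, ...] = _MALE_WILD_WEIGHTS
    moult_season_weights_f: tuple[float, ...] = _FEMALE_WILD_WEIGHTS
    #: days of year (0-based) of the release events: 5 June, 19 June, 17 July
    release_doys: tuple[int, ...] = (155, 169, 197)
    release_year: int = 2013
    liberty_days_mean: float = 344.0
    liberty_days_sd: float = 34.0
    #: additive Gaussian measurement error, applied before 0.1-mm rounding
    measurement_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for sex, k, L_inf, rng_ in (
            ("male", self.k_m, self.L_inf_m, self.release_size_range_m),
            ("female", self.k_f, self.L_inf_f, self.release_size_range_f),
        ):
            if not 0.0 < k < 3.0:
                raise InvalidParameterError(f"{sex} k must lie in (0, 3) yr^-1, got {k}")
            if not self.L_c < L_inf:
                raise InvalidParameterError(f"L_c must be below {sex} L_inf")
            if not (rng_[0] <= rng_[1] < L_inf):
                raise InvalidParameterError(
                    f"{sex} release size range {rng_} must lie strictly below L_inf={L_inf}"
                )
        if self.Z_over_k <= 0:
            raise InvalidParameterError("Z_over_k must be positive")
        for w in (self.moult_season_weights_m, self.moult_season_weights_f):
            arr = np.asarray(w, dtype=float)
            if arr.shape != (12,) or (arr < 0).any() or arr.sum() == 0:
                raise InvalidParameterError(
                    "moult season weights must be 12 non-negative values, not all zero"
                )
        if self.liberty_days_sd < 0 or self.liberty_days_mean <= 0:
            raise InvalidParameterError("liberty duration parameters must be positive")
        if self.measurement_sd < 0:
            raise InvalidParameterError("measurement_sd must be non-negative")

    # -- derived quantities -------------------------------------------------

    def p_second_moult(self, cl: float | np.ndarray) -> float | np.ndarray:
        """Size-dependent probability that a male moults twice in a year."""
        return np.clip(self.p_second_moult_intercept + self.p_second_moult_slope * np.asarray(cl), 0.0, 1.0)

    def mean_second_moult_probability(self) -> float:
        """Mean of p(CL) over the male release-size range (uniform releases)."""
        lo, hi = self.release_size_range_m
        grid = np.linspace(lo, hi, 513)
        return float(np.mean(self.p_second_moult(grid)))

    def envelope_time_per_moult(self, sex: str) -> float:
        """Years of VBGF envelope growth released by one moult.

        Chosen so the population-mean annual envelope advance is one year
        per year: females 1.0; males 1/(1 + p_bar + p_third).
        """
        if sex == "F":
            return 1.0
        p_bar = self.mean_second_moult_probability()
        return 1.0 / (1.0 + p_bar + self.p_third_moult)

    def params_for(self, sex: str) -> tuple[float, float]:
        """(L_inf, k) of the requested sex ('M' or 'F')."""
        if sex == "M":
            return self.L_inf_m, self.k_m
        if sex == "F":
            return self.L_inf_f, self.k_f
        raise InvalidParameterError(f"sex must be 'M' or 'F', got {sex!r}")

    def release_dates(self) -> list[_dt.date]:
        jan1 = _dt.date(self.release_year, 1, 1)
        return [jan1 + _dt.timedelta(days=int(d)) for d in self.release_doys]


@dataclass(frozen=True)
class Trajectory:
    """A single animal's stepped growth path.

    CL is piecewise constant: ``release_CL`` until the first moult, then
    ``post_moult_CLs[j]`` from ``moult_times[j]`` (days since release) on.
    """

    sex: str
    release_CL: float
    moult_times: np.ndarray
    post_moult_CLs: np.ndarray
    recapture_day: float

    def cl_at(self, day: float) -> float:
        """Carapace length on a given day since release."""
        idx = int(np.searchsorted(self.moult_times, day, side="right"))
        return self.release_CL if idx == 0 else float(self.post_moult_CLs[idx - 1])

    @property
    def final_CL(self) -> float:
        return self.cl_at(self.recapture_day)


def vbgf_envelope(L0, t, L_inf, k):
    """VBGF envelope length after ``t`` years of growth from ``L0``.

    L(t) = L_inf - (L_inf - L0) exp(-k t); monotone in t, -> L_inf.
    Accepts scalars or arrays (broadcast).
    """
    L0 = np.asarray(L0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(L0 < 0) or np.any(L0 >= L_inf):
        raise InvalidParameterError("release length must satisfy 0 <= L0 < L_inf")
    if np.any(t < 0):
        raise InvalidParameterError("time must be non-negative")
    # expm1 keeps the identity L(0) == L0 exact and resolves small increments
    out = L0 + (L_inf - L0) * (-np.expm1(-k * t))
    return float(out) if out.ndim == 0 else out


def stepped_growth(
    release_CL: float,
    moult_times,
    L_inf: float,
    k: float,
    recapture_day: float | None = None,
    envelope_times=None,
    sex: str = "M",
) -> Trajectory:
    """Discretize VBGF growth into moult-time jumps.

    By default each moult jumps the CL to the envelope evaluated at that
    calendar time, so the increment over any interval equals
    envelope(t_last_moult) - release_CL.  ``envelope_times`` (years) lets a
    caller decouple the growth clock from calendar moult times, e.g. to
    release a fixed fraction of a year of growth per moult.
    """
    moult_times = np.asarray(moult_times, dtype=float)
    if moult_times.size and (np.any(np.diff(moult_times) < 0) or moult_times[0] < 0):
        raise InvalidParameterError("moult_times must be sorted and non-negative")
    if envelope_times is None:
        envelope_times = moult_times / DAYS_PER_YEAR
    envelope_times = np.asarray(envelope_times, dtype=float)
    post = vbgf_envelope(release_CL, envelope_times, L_inf, k)
    post = np.atleast_1d(np.asarray(post, dtype=float))
    if recapture_day is None:
        recapture_day = float(moult_times[-1]) if moult_times.size else 0.0
    return Trajectory(sex, float(release_CL), moult_times, post, float(recapture_day))


def _sample_moult_doy(weights, rng: np.random.Generator) -> float:
    """Day of year (0-based, continuous) drawn from monthly weights."""
    w = np.asarray(weights, dtype=float)
    month = rng.choice(12, p=w / w.sum())
    lo, hi = _MONTH_STARTS[month], _MONTH_STARTS[month + 1]
    return float(lo + rng.uniform(0.0, hi - lo))


def _draw_moult_plan(sex, CL, config, rng, liberty_days, release_doy=None):
    """(moult days since release, annual moult count m) for one animal.

    The animal moults m times per year at intervals of 365.25/m days; its
    cycle phase comes from a seasonal draw, anchored to its own last moult
    (which may pre-date release), so the first post-release moult falls at
    the seasonal day modulo the inter-moult interval.
    """
    if release_doy is None:
        release_doy = config.release_doys[0]
    if sex == "F":
        m, weights = 1, config.moult_season_weights_f
    else:
        weights = config.moult_season_weights_m
        m = 1
        if rng.uniform() < config.p_second_moult(CL):
            m += 1
        if config.p_third_moult > 0 and rng.uniform() < config.p_third_moult:
            m += 1
    doy = _sample_moult_doy(weights, rng)
    first = (doy - release_doy) % 365.0
    interval = DAYS_PER_YEAR / m
    phase = first % interval
    times = np.arange(phase, liberty_days, interval)
    return times, m


def draw_moult_schedule(sex, CL, config: SimConfig, rng, liberty_days: float = DAYS_PER_YEAR,
                        release_doy: int | None = None):
    """Seasonal moult times (days since release) within a liberty period.

    Females moult exactly once per year; males once plus a second moult with
    probability p(CL), decreasing in CL.
    """
    times, _ = _draw_moult_plan(sex, CL, config, rng, liberty_days, release_doy)
    return times


def steady_state_cdf(L, L_inf: float, Z_over_k: float, L_c: float):
    """Closed-form CDF of the steady-state length distribution on [L_c, L_inf]."""
    L = np.clip(np.asarray(L, dtype=float), L_c, L_inf)
    return 1.0 - ((L_inf - L) / (L_inf - L_c)) ** Z_over_k


def sample_steady_state_lengths(L_inf, Z_over_k, L_c, n, rng) -> np.ndarray:
    """Lengths from the equilibrium population f(L) oc (L_inf - L)^(Z/k - 1).

    Constant recruitment + exponential mortality Z + VBGF growth give this
    density on [L_c, L_inf]; sampled by inversion,
    L = L_inf - (L_inf - L_c) (1 - u)^(1/(Z/k)).  By construction the sample
    satisfies the Beverton-Holt mean-length relation, so a Powell-Wetherall
    regression on it recovers L_inf.
    """
    if Z_over_k <= 0:
        raise InvalidParameterError("Z_over_k must be positive")
    if not L_c < L_inf:
        raise InvalidParameterError("L_c must be below L_inf")
    u = rng.uniform(size=int(n))
    return L_inf - (L_inf - L_c) * (1.0 - u) ** (1.0 / Z_over_k)


def _truncated_normal(mean, sd, n, rng, lower=1.0):
    """Normal(mean, sd) truncated below at ``lower`` via redraw."""
    if sd == 0:
        return np.full(n, float(mean))
    out = rng.normal(mean, sd, size=n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < lower
    return out


def simulate_individual(sex, L0, liberty_days, config: SimConfig, rng,
                        release_doy: int | None = None) -> Trajectory:
    """Stepped-growth trajectory of one tagged animal over its liberty period."""
    L_inf, k = config.params_for(sex)
    tau = config.envelope_time_per_moult(sex)
    times, _ = _draw_moult_plan(sex, L0, config, rng, liberty_days, release_doy)
    env_times = tau * np.arange(1, times.size + 1)
    return stepped_growth(L0, times, L_inf, k, recapture_day=liberty_days,
                          envelope_times=env_times, sex=sex)


def simulate_tag_recapture(config: SimConfig, n_individuals: int, rng=None) -> pd.DataFrame:
    """Tag-recapture records for ``n_individuals`` (sexes alternating).

    Release CLs are uniform on the sex-specific range, liberty durations
    Normal(mean, sd) truncated positive, and the recapture CL is the stepped
    final CL plus Gaussian measurement error, rounded to 0.1 mm.  Animals
    recaptured before their first moult show zero growth (before noise).
    """
    if n_individuals < 1:
        raise InvalidParameterError("n_individuals must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    releases = config.release_dates()
    tau = {s: config.envelope_time_per_moult(s) for s in "MF"}
    rows = []
    for i in range(int(n_individuals)):
        sex = "M" if i % 2 == 0 else "F"
        lo, hi = config.release_size_range_m if sex == "M" else config.release_size_range_f
        L0 = rng.uniform(lo, hi)
        release = releases[rng.integers(len(releases))]
        release_doy = (release - _dt.date(release.year, 1, 1)).days
        liberty = float(_truncated_normal(config.liberty_days_mean, config.liberty_days_sd, 1, rng)[0])
        L_inf, k = config.params_for(sex)
        times, _ = _draw_moult_plan(sex, L0, config, rng, liberty, release_doy)
        n_moults = times.size
        true_L2 = vbgf_envelope(L0, tau[sex] * n_moults, L_inf, k)
        L2 = true_L2 + (rng.normal(0.0, config.measurement_sd) if config.measurement_sd > 0 else 0.0)
        rows.append(
            {
                "tag_id": f"T{i:05d}",
                "sex": sex,
                "release_date": release.isoformat(),
                "release_cl_mm": round(L0, 1),
                "recapture_date": (release + _dt.timedelta(days=round(liberty))).isoformat(),
                "recapture_cl_mm": round(L2, 1),
                "n_moults": n_moults,
            }
        )
    return pd.DataFrame(rows)


def simulate_catch_lengths(config: SimConfig, n: int, sex: str, rng=None) -> np.ndarray:
    """Steady-state catch sample (raw lengths, mm CL) for one sex."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L_inf, _ = config.params_for(sex)
    return sample_steady_state_lengths(L_inf, config.Z_over_k, config.L_c, n, rng)


def simulate_captive_series(
    config: SimConfig,
    n_males: int = 111,
    n_females: int = 121,
    rng=None,
    p_moult_m: float = 47 / 111,
    p_moult_f: float = 63 / 121,
    skip_months: tuple[int, ...] = (3, 10),
) -> pd.DataFrame:
    """Monthly CL series for captive animals held for one year.

    Captive animals moult at most once; moulting probability and the small
    captive increments (~1-2 mm) mirror holding-tank observations, with male
    moults peaking Nov-Dec and female moults Apr-May.  Observations are
    monthly except ``skip_months`` (no March or October measurements).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    start = _dt.date(config.release_year + 1, 4, 1)
    obs_months = [(start.year + (start.month - 1 + j) // 12, (start.month - 1 + j) % 12 + 1) for j in range(12)]
    rows = []
    idx = 0
    for sex, n_sex, p_moult, weights in (
        ("M", n_males, p_moult_m, _MALE_CAPTIVE_WEIGHTS),
        ("F", n_females, p_moult_f, _FEMALE_CAPTIVE_WEIGHTS),
    ):
        lo, hi = (26.2, 53.0) if sex == "M" else (23.5, 41.2)
        for _ in range(int(n_sex)):
            L0 = round(rng.uniform(lo, hi), 1)
            moult_month = None
            if rng.uniform() < p_moult:
                w = np.asarray(weights, dtype=float)
                moult_month = int(rng.choice(12, p=w / w.sum())) + 1
            incr = round(rng.uniform(1.0, 2.0), 1)
            cl = L0
            moulted = False
            for year, month in obs_months:
                if month in skip_months:
                    continue
                flag = False
                if moult_month == month and not moulted:
                    cl, moulted, flag = round(L0 + incr, 1), True, True
                rows.append(
                    {
                        "tag_id": f"C{idx:05d}",
                        "sex": sex,
                        "obs_date": _dt.date(year, month, 15).isoformat(),
                        "cl_mm": cl,
                        "moult_flag": flag,
                    }
                )
            idx += 1
    return pd.DataFrame(rows)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
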