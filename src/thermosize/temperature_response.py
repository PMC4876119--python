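"""Temperature-response inference for bacterioplankton size, NAC and growth.

Implements the study's core statistics:

* per-bottle experiment means of cell volume and nucleic-acid content
  (NAC), taken over all time points of an incubation (with growth-phase
  and maximum-abundance alternatives for robustness checks);
* OLS regression of those means against incubation temperature (the
  temperature-response slope, normally n = 9: three replicates at three
  temperatures), with closed-form standard errors and a 95% t confidence
  interval (df = n - 2); a slope is "significant" when the CI excludes 0;
* normalization to percent change per degC (positive = reduction) against
  the ambient t = 0 value, and conversion of NAC percent loss to base
  pairs per degC via genome-size anchors (LNA = 2 Mbp, HNA = 5 Mbp);
* growth rates as the OLS slope of ln abundance vs time over an
  automatically selected linear (exponential-phase) window;
* activation energies from Arrhenius plots (ln rate vs 1/kT), reported so
  that positive E means faster growth when warmer;
* Pearson cross-correlations between monthly slope series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .constants import BOLTZMANN_EV, KELVIN_OFFSET

__all__ = [
    "TemperatureResponse",
    "GrowthFit",
    "ArrheniusFit",
    "GenomeAnchor",
    "bottle_means",
    "ambient_reference",
    "fit_temperature_slope",
    "percent_per_degC",
    "nac_to_basepairs",
    "fit_growth_rate",
    "activation_energy",
    "correlate_responses",
    "monthly_slopes",
    "annual_summary",
    "correlation_matrix",
    "growth_table",
    "arrhenius_table",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperatureResponse:
    """OLS slope of a per-bottle summary against incubation temperature."""

    slope: float
    stderr: float
    ci_low: float
    ci_high: float
    n: int
    r_squared: float
    significant: bool
    response: str = ""
    percent_per_degC: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("confidence interval must contain the slope")


@dataclass(frozen=True)
class GrowthFit:
    """Exponential-phase growth rate from ln abundance vs time."""

    rate_per_day: float
    window: tuple[int, int]  # inclusive indices into the time series
    r_squared: float
    temperature_C: float | None = None
    below_threshold: bool = False
    non_positive: bool = False


@dataclass(frozen=True)
class ArrheniusFit:
    """Activation energy from an Arrhenius plot of growth rates.

    ``activation_energy_eV`` is the negated regression slope of ln(rate)
    on 1/(kT), so positive values mean growth accelerates with warming.
    """

    activation_energy_eV: float
    slope: float
    stderr: float
    n: int
    temperatures_K: tuple[float, ...]
    boltzmann_eV_per_K: float = BOLTZMANN_EV


@dataclass(frozen=True)
class GenomeAnchor:
    """Genome sizes (Mbp) anchoring the NAC scale of each cytometric group,
    from the bimodal distribution of bacterial genome sizes."""

    anchors_Mbp: Mapping[str, float] = field(
        default_factory=lambda: {"LNA": 2.0, "HNA": 5.0}
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.anchors_Mbp.values()):
            raise ValueError("genome anchors must be positive")


# ---------------------------------------------------------------------------
# Bottle summaries
# ---------------------------------------------------------------------------

_BOTTLE_KEYS = ["month", "treatment", "temperature_offset", "temperature_C",
                "replicate", "group"]


def bottle_means(stats: pd.DataFrame) -> pd.DataFrame:
    """Collapse a tidy per-time-point stats table to per-bottle means.

    Expects columns ``month, treatment, temperature_offset, temperature_C,
    replicate, time_d, group, mean_volume_um3, mean_gf_fru`` and (for the
    growth-phase alternatives) ``abundance_per_mL``. Returns one row per
    bottle x group with the unweighted mean over all time points, plus the
    growth-phase-only mean and the value at the time of maximum abundance.
    Bottles with < 2 usable time points are rejected.
    """
    rows = []
    for key, sub in stats.groupby(_BOTTLE_KEYS, sort=True):
        sub = sub.sort_values("time_d")
        ok = sub["mean_volume_um3"].notna() & sub["mean_gf_fru"].notna()
        if ok.sum() < len(sub):
            warnings.warn(f"bottle {key}: {int((~ok).sum())} time points missing",
                          stacklevel=2)
        sub = sub[ok]
        if len(sub) < 2:
            raise ValueError(f"bottle {key}: need >= 2 time points")
        row = dict(zip(_BOTTLE_KEYS, key))
        row["n_times"] = len(sub)
        row["mean_volume_um3"] = float(sub["mean_volume_um3"].mean())
        row["mean_nac_fru"] = float(sub["mean_gf_fru"].mean())
        if "abundance_per_mL" in sub.columns and sub["abundance_per_mL"].gt(0).all():
            t = sub["time_d"].to_numpy(float)
            n = sub["abundance_per_mL"].to_numpy(float)
            fit = fit_growth_rate(t, n)
            i, j = fit.window
            gp = sub.iloc[i : j + 1]
            row["growth_rate_per_day"] = fit.rate_per_day
            row["growth_r_squared"] = fit.r_squared
            row["growth_below_threshold"] = fit.below_threshold
            row["growth_non_positive"] = fit.non_positive
            row["growthphase_volume_um3"] = (
                float(gp["mean_volume_um3"].mean()) if not fit.non_positive else np.nan
            )
            row["growthphase_nac_fru"] = (
                float(gp["mean_gf_fru"].mean()) if not fit.non_positive else np.nan
            )
            imax = int(np.argmax(n))
            row["maxabundance_volume_um3"] = float(sub["mean_volume_um3"].iloc[imax])
            row["maxabundance_nac_fru"] = float(sub["mean_gf_fru"].iloc[imax])
        rows.append(row)
    return pd.DataFrame(rows)


def ambient_reference(stats: pd.DataFrame, mode: str = "ambient") -> pd.DataFrame:
    """Reference values for percent-per-degC normalization.

    ``mode="ambient"`` (default): mean over replicates of the t = 0 values
    of the ambient-temperature (offset 0) bottles, per month x treatment x
    group. ``mode="initial"``: t = 0 values averaged over *all* bottles of
    the cell (the normalization-choice robustness alternative).
    """
    if mode not in ("ambient", "initial"):
        raise ValueError("mode must be 'ambient' or 'initial'")
    t0 = stats[stats["time_d"] == stats["time_d"].min()]
    if mode == "ambient":
        t0 = t0[t0["temperature_offset"] == 0]
    out = (
        t0.groupby(["month", "treatment", "group"], sort=True)[
            ["mean_volume_um3", "mean_gf_fru"]
        ]
        .mean()
        .rename(columns={"mean_volume_um3": "ambient_volume_um3",
                         "mean_gf_fru": "ambient_nac_fru"})
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# Slopes
# ---------------------------------------------------------------------------


def fit_temperature_slope(
    temperatures: Sequence[float],
    values: Sequence[float],
    response: str = "",
    ambient_value: float | None = None,
    alpha: float = 0.05,
) -> TemperatureResponse:
    """OLS slope of a bottle summary vs temperature with a 95% t CI.

    Requires >= 3 points and >= 2 distinct temperatures. If
    ``ambient_value`` is given the percent change per degC is attached.
    """
    x = np.asarray(temperatures, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValueError("temperatures and values must be paired")
    if x.size < 3:
        raise ValueError("need >= 3 bottles for a slope")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct temperatures")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    tcrit = float(sps.t.ppf(1 - alpha / 2, x.size - 2))
    lo, hi = slope - tcrit * se, slope + tcrit * se
    pct = percent_per_degC(slope, ambient_value) if ambient_value is not None else None
    return TemperatureResponse(
        slope=slope, stderr=se, ci_low=lo, ci_high=hi, n=int(x.size),
        r_squared=float(res.rsquared), significant=bool(lo > 0 or hi < 0),
        response=response, percent_per_degC=pct,
    )


def percent_per_degC(slope: float, ambient_value: float) -> float:
    """Percent change per degC, normalized to the ambient value.

    Positive values mean *reduction* with warming (the slope sign is
    flipped), matching the convention in which the headline numbers are
    percent decreases. Invariant under any common rescaling of slope and
    ambient value.
    """
    if ambient_value <= 0:
        raise ValueError("ambient value must be positive")
    return -100.0 * slope / ambient_value


def nac_to_basepairs(
    percent_per_degC_value: float,
    group: str,
    anchor: GenomeAnchor | None = None,
) -> float:
    """Convert a NAC percent loss per degC into kbp per degC.

    The group's ambient NAC is equated to its genome anchor (2 Mbp for
    LNA, 5 Mbp for HNA), so kbp/degC = percent/100 * anchor_Mbp * 1000.
    """
    if not np.isfinite(percent_per_degC_value):
        raise ValueError("percent must be finite")
    anchor = anchor or GenomeAnchor()
    if group not in anchor.anchors_Mbp:
        raise KeyError(f"unknown group {group!r}")
    return percent_per_degC_value / 100.0 * anchor.anchors_Mbp[group] * 1000.0


# ---------------------------------------------------------------------------
# Growth rates and activation energy
# ---------------------------------------------------------------------------


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, r_squared) by closed form; flat-y windows get r^2 = 1."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    resid = y - (ym + slope * (x - xm))
    ssr = float((resid**2).sum())
    sst = float(((y - ym) ** 2).sum())
    if sst <= 1e-300:
        return slope, 1.0 if ssr <= 1e-300 else 0.0
    return slope, 1.0 - ssr / sst


def fit_growth_rate(
    times: Sequence[float],
    abundances: Sequence[float],
    min_window: int = 3,
    r2_threshold: float = 0.95,
    temperature_C: float | None = None,
) -> GrowthFit:
    """Growth rate as the OLS slope of ln N vs t over the linear phase.

    The linear (exponential) phase is found by exhaustive search over
    contiguous windows of >= ``min_window`` points: among windows with
    r^2 >= ``r2_threshold`` the one with the largest slope wins, ties
    broken by longer window then earlier start. If no window meets the
    threshold the best-slope window is returned flagged
    ``below_threshold``; a non-positive winning slope is flagged
    ``non_positive`` (e.g. monotone-declining series).
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(abundances, dtype=float)
    if t.size != n.size or t.size < 4:
        raise ValueError("need >= 4 paired time points")
    if np.any(n <= 0):
        raise ValueError("abundances must be positive")
    y = np.log(n)
    ok_windows, all_windows = [], []
    for i, j in combinations(range(t.size + 1), 2):
        if j - i < min_window:
            continue
        slope, r2 = _ols_line(t[i:j], y[i:j])
        cand = ((i, j - 1), slope, r2)
        all_windows.append(cand)
        if r2 >= r2_threshold:
            ok_windows.append(cand)
    pool = ok_windows if ok_windows else all_windows
    # max slope; near-ties (within 1e-9 relative) resolved by longer
    # window, then earlier start
    smax = max(c[1] for c in pool)
    tol = 1e-9 * max(1.0, abs(smax))
    window, slope, r2 = max(
        (c for c in pool if c[1] >= smax - tol),
        key=lambda c: (c[0][1] - c[0][0], -c[0][0]),
    )
    return GrowthFit(
        rate_per_day=float(slope), window=window, r_squared=float(r2),
        temperature_C=temperature_C,
        below_threshold=not ok_windows,
        non_positive=slope <= 0,
    )


def activation_energy(
    rates_per_day: Sequence[float],
    temperatures_C: Sequence[float],
) -> ArrheniusFit:
    """Arrhenius activation energy from growth rates at >= 2 temperatures.

    Non-positive rates are dropped with a warning; ln(rate) is regressed
    on 1/(kT) and E is the negated slope (positive E = faster growth when
    warmer).
    """
    mu = np.asarray(rates_per_day, dtype=float)
    tc = np.asarray(temperatures_C, dtype=float)
    if mu.size != tc.size:
        raise ValueError("rates and temperatures must be paired")
    keep = mu > 0
    if keep.sum() < mu.size:
        warnings.warn(f"dropping {int((~keep).sum())} non-positive growth rates",
                      stacklevel=2)
    mu, tc = mu[keep], tc[keep]
    tk = tc + KELVIN_OFFSET
    if np.unique(tk).size < 2:
        raise ValueError("need positive rates at >= 2 distinct temperatures")
    x = 1.0 / (BOLTZMANN_EV * tk)
    res = sm.OLS(np.log(mu), sm.add_constant(x)).fit()
    slope = float(res.params[1])
    se = float(res.bse[1]) if mu.size > 2 else np.nan
    return ArrheniusFit(
        activation_energy_eV=-slope, slope=slope, stderr=se,
        n=int(mu.size), temperatures_K=tuple(np.sort(np.unique(tk))),
    )


# ---------------------------------------------------------------------------
# Cross-correlations of monthly responses
# ---------------------------------------------------------------------------


def correlate_responses(a: Sequence[float], b: Sequence[float]):
    """Pearson r with a two-sided t-approximation p value.

    Returns ``(r, p, n)``; zero variance in either series yields
    ``(nan, nan, n)`` with a warning.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return np.nan, np.nan, int(x.size)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


# ---------------------------------------------------------------------------
# Tidy-table drivers
# ---------------------------------------------------------------------------


def monthly_slopes(
    summaries: pd.DataFrame,
    ambient: pd.DataFrame | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Temperature-response slopes per month x treatment x group x response.

    ``summaries`` is a bottle-mean table (``bottle_means`` output or the
    moment-level simulator's); ``ambient`` optionally supplies
    per-(month, treatment, group) ambient values for the percent scale.
    Cells with fewer than ``min_n`` bottles are skipped with a warning.
    """
    amb_idx = None
    if ambient is not None:
        amb_idx = ambient.set_index(["month", "treatment", "group"])
    responses = {"volume": "mean_volume_um3", "nac": "mean_nac_fru"}
    rows = []
    for (month, treatment, group), sub in summaries.groupby(
        ["month", "treatment", "group"], sort=True
    ):
        if len(sub) < min_n:
            warnings.warn(
                f"{month}/{treatment}/{group}: only {len(sub)} bottles, skipped",
                stacklevel=2,
            )
            continue
        for response, col in responses.items():
            amb_val = None
            if amb_idx is not None:
                amb_col = "ambient_volume_um3" if response == "volume" else "ambient_nac_fru"
                amb_val = float(amb_idx.loc[(month, treatment, group), amb_col])
            fit = fit_temperature_slope(
                sub["temperature_C"], sub[col], response=response,
                ambient_value=amb_val,
            )
            rows.append(dict(
                month=month, treatment=treatment, group=group, response=response,
                slope=fit.slope, stderr=fit.stderr, ci_low=fit.ci_low,
                ci_high=fit.ci_high, n=fit.n, r_squared=fit.r_squared,
                significant=fit.significant,
                percent_per_degC=fit.percent_per_degC,
            ))
    return pd.DataFrame(rows)


def annual_summary(monthly: pd.DataFrame) -> pd.DataFrame:
    """Annual mean +/- SE of monthly slopes per treatment x group x response."""
    rows = []
    for (treatment, group, response), sub in monthly.groupby(
        ["treatment", "group", "response"], sort=True
    ):
        n = len(sub)
        rows.append(dict(
            treatment=treatment, group=group, response=response, n_months=n,
            mean_slope=float(sub["slope"].mean()),
            se_slope=float(sub["slope"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            mean_percent_per_degC=(
                float(sub["percent_per_degC"].mean())
                if sub["percent_per_degC"].notna().all() else np.nan
            ),
            se_percent_per_degC=(
                float(sub["percent_per_degC"].std(ddof=1) / np.sqrt(n))
                if n > 1 and sub["percent_per_degC"].notna().all() else np.nan
            ),
            n_significant=int(sub["significant"].sum()),
        ))
    return pd.DataFrame(rows)


def correlation_matrix(monthly: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """8 x 8 Pearson matrix over {volume, nac} x {HNA, LNA} x {C, F}.

    Returns ``(r, p)`` DataFrames indexed by "response/group/treatment"
    labels; series pairs sharing fewer than 3 months are NaN.
    """
    wide = monthly.pivot_table(
        index="month", columns=["response", "group", "treatment"], values="slope"
    )
    cols = list(wide.columns)
    labels = ["/".join(c) for c in cols]
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = wide.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                continue
            a, b = pair.iloc[:, 0], pair.iloc[:, 1]
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            if a.std() == 0 or b.std() == 0:
                continue
            rr, pp = sps.pearsonr(a, b)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (pd.DataFrame(r, index=labels, columns=labels),
            pd.DataFrame(p, index=labels, columns=labels))


def growth_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Per-bottle x group growth fits from the tidy stats table."""
    rows = []
    for key, sub in stats.groupby(_BOTTLE_KEYS, sort=True):
        sub = sub.sort_values("time_d")
        ok = sub["abundance_per_mL"] > 0
        if ok.sum() < 4:
            continue
        sub = sub[ok]
        fit = fit_growth_rate(
            sub["time_d"].to_numpy(float), sub["abundance_per_mL"].to_numpy(float),
            temperature_C=float(sub["temperature_C"].iloc[0]),
        )
        row = dict(zip(_BOTTLE_KEYS, key))
        row.update(
            rate_per_day=fit.rate_per_day, r_squared=fit.r_squared,
            window_start=fit.window[0], window_end=fit.window[1],
            below_threshold=fit.below_threshold, non_positive=fit.non_positive,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def arrhenius_table(growth: pd.DataFrame) -> pd.DataFrame:
    """Activation energies per month x treatment x group from growth fits."""
    rows = []
    for (month, treatment, group), sub in growth.groupby(
        ["month", "treatment", "group"], sort=True
    ):
        usable = sub[sub["rate_per_day"] > 0]
        if usable["temperature_C"].nunique() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = activation_energy(usable["rate_per_day"], usable["temperature_C"])
        rows.append(dict(
            month=month, treatment=treatment, group=group,
            activation_energy_eV=fit.activation_energy_eV,
            stderr=fit.stderr, n=fit.n,
        ))
    return pd.DataFrame(rows)
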