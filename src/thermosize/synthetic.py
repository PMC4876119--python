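"""Synthetic warming-incubation experiments with known ground truth.

Emulates a year-round seawater incubation study: every month, surface water
is split into a whole-community (C) and a 0.8 um pre-filtered (F)
treatment, incubated in triplicate at three temperatures (ambient - 3,
ambient, ambient + 3 degC), and sampled once or twice a day for about a
week. Each sampling produces a flow-cytometry event cloud with three
log-normal clusters (LNA bacteria, HNA bacteria, 1 um reference beads),
per-bottle abundance trajectories with lag / exponential / saturation
phases whose exponential rate follows a Boltzmann-Arrhenius law, linear
per-degC effects injected on mean cell volume and nucleic-acid content
(NAC), and companion CARD-FISH count tables and ARISA peak tables.

Everything is driven by a single master seed split deterministically into
per-bottle substreams, so identical (design, truth, seed) triples produce
identical output, while replicates remain independent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import BOLTZMANN_EV, KELVIN_OFFSET, SPHERE_FACTOR
from .cytometry import CalibrationModel, default_size_calibration

__all__ = [
    "MONTHS",
    "ExperimentDesign",
    "GrowthTruth",
    "PopulationTruth",
    "BeadTruth",
    "TruthParams",
    "CommunityTruth",
    "ClusterSpec",
    "default_design",
    "default_truth",
    "default_community_truth",
    "arrhenius_rate",
    "abundance_at",
    "generate_cytogram",
    "generate_experiment",
    "generate_community_tables",
    "simulate_bottle_summaries",
    "solve_log_correlation",
    "single_cluster_log_correlation",
    "SyntheticExperiment",
]

MONTHS = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

# Seasonal surface temperatures typical of a southern Bay of Biscay shelf
# station (degC).
DEFAULT_AMBIENT_T = {
    "Jan": 13.2, "Feb": 12.8, "Mar": 13.0, "Apr": 13.5, "May": 14.5,
    "Jun": 16.0, "Jul": 18.0, "Aug": 19.5, "Sep": 19.0, "Oct": 17.5,
    "Nov": 15.5, "Dec": 14.0,
}

GROUPS = ("LNA", "HNA")
TREATMENTS = ("C", "F")


# ---------------------------------------------------------------------------
# Design and truth parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Incubation design: months x treatments x temperatures x replicates."""

    months: tuple[str, ...] = MONTHS
    treatments: tuple[str, ...] = TREATMENTS
    temperature_offsets_degC: tuple[float, ...] = (-3.0, 0.0, 3.0)
    ambient_temperature_degC: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMBIENT_T)
    )
    replicates: int = 3
    sampling_times_days: tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0,
    )
    photoperiod_h: Mapping[str, float] | None = None  # carried, unused

    def __post_init__(self) -> None:
        offs = self.temperature_offsets_degC
        if len(offs) < 2 or any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("need >= 2 strictly increasing temperature offsets")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        t = self.sampling_times_days
        if t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sampling times must start at 0 and strictly increase")
        missing = [m for m in self.months if m not in self.ambient_temperature_degC]
        if missing:
            raise ValueError(f"no ambient temperature for months {missing}")

    def temperature(self, month: str, offset: float) -> float:
        return self.ambient_temperature_degC[month] + offset

    def bottles(self) -> Iterator[tuple[str, str, float, int]]:
        for month in self.months:
            for treatment in self.treatments:
                for offset in self.temperature_offsets_degC:
                    for rep in range(1, self.replicates + 1):
                        yield month, treatment, offset, rep


@dataclass(frozen=True)
class GrowthTruth:
    """Lag -> exponential (Arrhenius rate) -> saturation growth parameters."""

    mu_ref_per_day: float
    activation_energy_eV: float
    lag_days: float = 1.0
    carrying_capacity_per_mL: float = 2.0e6
    initial_abundance_per_mL: float = 3.0e5

    def __post_init__(self) -> None:
        if self.mu_ref_per_day <= 0:
            raise ValueError("mu_ref must be positive")
        if self.initial_abundance_per_mL <= 0:
            raise ValueError("initial abundance must be positive")
        if self.carrying_capacity_per_mL <= self.initial_abundance_per_mL:
            raise ValueError("carrying capacity must exceed initial abundance")
        if self.lag_days < 0:
            raise ValueError("lag must be >= 0")


@dataclass(frozen=True)
class PopulationTruth:
    """Injected truth for one bacterial group in one treatment."""

    ambient_volume_um3: float
    ambient_nac_fru: float
    size_slope_um3_per_degC: float
    nac_slope_fru_per_degC: float
    ssc_log_sd: float
    gf_log_sd: float
    growth: GrowthTruth
    monthly_size_slope_sd: float = 0.0
    monthly_nac_slope_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.ambient_volume_um3 <= 0 or self.ambient_nac_fru <= 0:
            raise ValueError("ambient volume and NAC must be positive")
        if self.ssc_log_sd < 0 or self.gf_log_sd < 0:
            raise ValueError("dispersions must be >= 0")


@dataclass(frozen=True)
class BeadTruth:
    """Nominal raw-signal position and spread of the 1 um reference beads."""

    ssc_raw: float = 520.0
    gf_raw: float = 480.0
    cv: float = 0.05
    n_events: int = 300

    def __post_init__(self) -> None:
        if self.ssc_raw <= 0 or self.gf_raw <= 0 or self.cv < 0 or self.n_events < 0:
            raise ValueError("invalid bead parameters")


@dataclass(frozen=True)
class TruthParams:
    """Full ground-truth parameter set for one synthetic year."""

    populations: Mapping[tuple[str, str], PopulationTruth]
    size_nac_correlation: float = 0.82  # pooled-event Pearson target
    slope_pair_correlation: float = 0.75  # size vs NAC monthly slope deviations
    bead: BeadTruth = field(default_factory=BeadTruth)
    calibration: CalibrationModel = field(default_factory=default_size_calibration)
    n_target_events: int = 3000
    bottle_sd_frac: float = 0.05
    time_sd_frac: float = 0.03
    abundance_cv: float = 0.05
    gain_sd: float = 0.10
    lag_drift_frac: float = 0.02
    growth_drift_frac: float = 0.03
    poisson_counts: bool = True

    def __post_init__(self) -> None:
        if not -1.0 <= self.size_nac_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if not -1.0 <= self.slope_pair_correlation <= 1.0:
            raise ValueError("slope correlation must lie in [-1, 1]")
        for treatment in {t for _, t in self.populations}:
            lna = self.populations.get(("LNA", treatment))
            hna = self.populations.get(("HNA", treatment))
            if lna and hna and hna.ambient_nac_fru <= lna.ambient_nac_fru:
                raise ValueError(
                    f"HNA ambient NAC must exceed LNA ambient NAC ({treatment})"
                )

    def zero_noise(self) -> "TruthParams":
        """Copy with all stochastic components switched off (point masses)."""
        pops = {
            key: replace(p, ssc_log_sd=0.0, gf_log_sd=0.0,
                         monthly_size_slope_sd=0.0, monthly_nac_slope_sd=0.0)
            for key, p in self.populations.items()
        }
        return replace(
            self, populations=pops, bead=replace(self.bead, cv=0.0),
            bottle_sd_frac=0.0, time_sd_frac=0.0, abundance_cv=0.0,
            gain_sd=0.0, lag_drift_frac=0.0, growth_drift_frac=0.0,
            poisson_counts=False,
        )


def default_design() -> ExperimentDesign:
    return ExperimentDesign()


def default_truth() -> TruthParams:
    """Study-condition defaults.

    Annual-mean per-degC slopes follow the printed group x treatment table
    (size: HNA F -4.2e-3, LNA F -1.6e-3, HNA C -5.3e-3, LNA C -0.5e-3
    um^3/degC; NAC: -2.2e-3, -1.2e-3, -4.4e-3, -0.4e-3 fru/degC); true
    monthly slopes scatter around those means with SD equal to the printed
    annual-mean standard errors. Ambient volumes sit in the printed
    0.035-0.091 um^3 range and HNA NAC is 70% above LNA NAC. Cluster
    dispersions are chosen so the pooled size-NAC correlation target (0.82)
    is attainable and the HNA/LNA fluorescence modes stay separable.
    """
    size = {("HNA", "F"): (-4.2e-3, 1.7e-3), ("LNA", "F"): (-1.6e-3, 1.0e-3),
            ("HNA", "C"): (-5.3e-3, 1.2e-3), ("LNA", "C"): (-0.5e-3, 0.7e-3)}
    nac = {("HNA", "F"): (-2.2e-3, 1.5e-3), ("LNA", "F"): (-1.2e-3, 0.5e-3),
           ("HNA", "C"): (-4.4e-3, 0.8e-3), ("LNA", "C"): (-0.4e-3, 0.6e-3)}
    ambient = {"LNA": (0.045, 0.025), "HNA": (0.055, 0.0425)}
    growth = {
        ("LNA", "C"): GrowthTruth(0.40, 0.30),
        ("HNA", "C"): GrowthTruth(0.80, 0.65),
        ("LNA", "F"): GrowthTruth(0.50, 0.35),
        ("HNA", "F"): GrowthTruth(0.90, 0.65),
    }
    pops = {}
    for group in GROUPS:
        for treatment in TREATMENTS:
            vol, fl = ambient[group]
            s, s_se = size[(group, treatment)]
            m, m_se = nac[(group, treatment)]
            pops[(group, treatment)] = PopulationTruth(
                ambient_volume_um3=vol,
                ambient_nac_fru=fl,
                size_slope_um3_per_degC=s,
                nac_slope_fru_per_degC=m,
                ssc_log_sd=0.08,
                gf_log_sd=0.08,
                growth=growth[(group, treatment)],
                monthly_size_slope_sd=s_se,
                monthly_nac_slope_sd=m_se,
            )
    return TruthParams(populations=pops)


# ---------------------------------------------------------------------------
# Growth law
# ---------------------------------------------------------------------------


def arrhenius_rate(mu_ref: float, activation_energy_eV: float,
                   temperature_C: float, reference_C: float) -> float:
    """Boltzmann-Arrhenius growth rate, mu_ref at the reference temperature."""
    t = temperature_C + KELVIN_OFFSET
    tr = reference_C + KELVIN_OFFSET
    return mu_ref * np.exp(-(activation_energy_eV / BOLTZMANN_EV) * (1 / t - 1 / tr))


def abundance_at(t, growth: GrowthTruth, temperature_C: float,
                 reference_C: float):
    """Deterministic abundance: flat lag, exponential rise, cap at K.

    Saturation is an abrupt carrying-capacity cap (the sharp limit of a
    logistic), so ln N is exactly linear over the whole exponential phase
    with slope equal to the Arrhenius rate at the bottle's temperature.
    """
    t = np.asarray(t, dtype=float)
    mu = arrhenius_rate(growth.mu_ref_per_day, growth.activation_energy_eV,
                        temperature_C, reference_C)
    n = growth.initial_abundance_per_mL * np.exp(mu * np.maximum(t - growth.lag_days, 0.0))
    return np.minimum(n, growth.carrying_capacity_per_mL), mu


def _phase(t: float, growth: GrowthTruth, mu: float) -> str:
    if t < growth.lag_days:
        return "lag"
    t_sat = growth.lag_days + np.log(
        growth.carrying_capacity_per_mL / growth.initial_abundance_per_mL
    ) / mu
    return "exponential" if t < t_sat else "stationary"


# ---------------------------------------------------------------------------
# Event-cloud generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSpec:
    """One log-normal event cluster, located by its arithmetic means."""

    name: str
    n: int
    mean_ssc: float
    mean_gf: float
    ssc_log_sd: float
    gf_log_sd: float
    log_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cluster size must be >= 0")
        if self.mean_ssc <= 0 or self.mean_gf <= 0:
            raise ValueError("cluster locations must be positive")
        if self.ssc_log_sd < 0 or self.gf_log_sd < 0:
            raise ValueError("dispersions must be >= 0")
        if not -1.0 <= self.log_correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


def _volume_log_sd(ssc_log_sd: float, calibration: CalibrationModel) -> float:
    # V = (pi/6) a^3 ssc^(3b): log-normal with log-sd 3b * ssc_log_sd
    _, b = calibration.coefficients
    return 3.0 * b * ssc_log_sd


def mean_ssc_for_volume(mean_volume: float, ssc_log_sd: float,
                        calibration: CalibrationModel) -> float:
    """Arithmetic-mean scatter whose per-event spherical volumes average to
    ``mean_volume`` given the cluster's log-scale dispersion."""
    a, b = calibration.coefficients
    p = 3.0 * b
    c = SPHERE_FACTOR * a**3
    # ln ssc ~ N(m, s^2) with m = ln(mean_ssc) - s^2/2;
    # E[V] = c * exp(p*m + p^2 s^2 / 2)
    m = (np.log(mean_volume / c) - (p * ssc_log_sd) ** 2 / 2.0) / p
    return float(np.exp(m + ssc_log_sd**2 / 2.0))


def _cluster_vf_moments(spec: ClusterSpec, calibration: CalibrationModel):
    """(E[V], E[F], volume log-sd, fluorescence log-sd) for one cluster."""
    a, b = calibration.coefficients
    p = 3.0 * b
    c = SPHERE_FACTOR * a**3
    m_s = np.log(spec.mean_ssc) - spec.ssc_log_sd**2 / 2.0
    ev = c * np.exp(p * m_s + (p * spec.ssc_log_sd) ** 2 / 2.0)
    return ev, spec.mean_gf, p * spec.ssc_log_sd, spec.gf_log_sd


def single_cluster_log_correlation(sv: float, sf: float, target_r: float) -> float:
    """Gaussian (log-scale) correlation giving linear Pearson ``target_r``
    between a log-normal pair with log-sds ``sv``, ``sf``."""
    if sv == 0 or sf == 0:
        return 0.0
    span = np.sqrt(np.expm1(sv**2) * np.expm1(sf**2))
    arg = 1.0 + target_r * span
    if arg <= 0:
        return -1.0
    return float(np.clip(np.log(arg) / (sv * sf), -1.0, 1.0))


def solve_log_correlation(
    clusters: Sequence[ClusterSpec],
    target_r: float,
    calibration: CalibrationModel,
    weights: Sequence[float] | None = None,
) -> float:
    """Within-cluster Gaussian correlation making the *pooled* linear Pearson
    between per-event volume and fluorescence equal ``target_r``.

    Pooled mixture moments of the log-normal clusters are available in
    closed form, so the (monotone) pooled correlation is inverted with a
    root finder. If the target is unreachable (the between-cluster geometry
    alone already fixes the pooled correlation outside the attainable band)
    the nearest endpoint is returned with a warning.
    """
    live = [c for c in clusters if c.n > 0]
    if weights is None:
        w = np.array([c.n for c in live], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if len(live) == 0:
        raise ValueError("no events in any cluster")
    w = w / w.sum()
    moments = [_cluster_vf_moments(c, calibration) for c in live]
    if len(live) == 1:
        _, _, sv, sf = moments[0]
        return single_cluster_log_correlation(sv, sf, target_r)

    ev = sum(wi * m[0] for wi, m in zip(w, moments))
    ef = sum(wi * m[1] for wi, m in zip(w, moments))
    var_v = sum(wi * m[0] ** 2 * np.exp(m[2] ** 2) for wi, m in zip(w, moments)) - ev**2
    var_f = sum(wi * m[1] ** 2 * np.exp(m[3] ** 2) for wi, m in zip(w, moments)) - ef**2
    if var_v <= 0 or var_f <= 0:
        return 0.0
    denom = np.sqrt(var_v * var_f)

    def pooled_r(rho: float) -> float:
        cov = sum(
            wi * m[0] * m[1] * np.exp(rho * m[2] * m[3]) for wi, m in zip(w, moments)
        ) - ev * ef
        return cov / denom

    lo, hi = pooled_r(-1.0), pooled_r(1.0)
    if target_r <= lo:
        warnings.warn("pooled correlation target below attainable range", stacklevel=2)
        return -1.0
    if target_r >= hi:
        warnings.warn("pooled correlation target above attainable range", stacklevel=2)
        return 1.0
    return float(brentq(lambda r: pooled_r(r) - target_r, -1.0, 1.0, xtol=1e-12))


def generate_cytogram(
    clusters: Sequence[ClusterSpec],
    bead: BeadTruth | None = None,
    seed: int | np.random.Generator = 0,
    gain: float = 1.0,
) -> pd.DataFrame:
    """Draw one event table from log-normal clusters (plus optional beads).

    Cluster locations are arithmetic means in whatever units the caller
    works in; ``gain`` rescales both channels of every event (instrument
    gain). Hidden truth labels are stored in column ``true_label``. If both
    an LNA and an HNA cluster are present the HNA fluorescence location
    must exceed the LNA one.
    """
    by_name = {c.name: c for c in clusters}
    if "LNA" in by_name and "HNA" in by_name:
        if by_name["HNA"].mean_gf <= by_name["LNA"].mean_gf:
            raise ValueError("HNA fluorescence location must exceed LNA location")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for c in clusters:
        if c.n == 0:
            continue
        m_s = np.log(c.mean_ssc) - c.ssc_log_sd**2 / 2.0
        m_g = np.log(c.mean_gf) - c.gf_log_sd**2 / 2.0
        z = rng.standard_normal((c.n, 2))
        z2 = c.log_correlation * z[:, 0] + np.sqrt(1 - c.log_correlation**2) * z[:, 1]
        ssc = np.exp(m_s + c.ssc_log_sd * z[:, 0])
        gf = np.exp(m_g + c.gf_log_sd * z2)
        frames.append(pd.DataFrame({"ssc": ssc, "gf": gf, "true_label": c.name}))
    if bead is not None and bead.n_events > 0:
        s = np.sqrt(np.log1p(bead.cv**2))
        z = rng.standard_normal((bead.n_events, 2))
        ssc = np.exp(np.log(bead.ssc_raw) - s**2 / 2.0 + s * z[:, 0])
        gf = np.exp(np.log(bead.gf_raw) - s**2 / 2.0 + s * z[:, 1])
        frames.append(pd.DataFrame({"ssc": ssc, "gf": gf, "true_label": "bead"}))
    if not frames:
        raise ValueError("cytogram must contain at least one event")
    out = pd.concat(frames, ignore_index=True)
    out[["ssc", "gf"]] *= gain
    return out


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------


@dataclass
class Acquisition:
    """Parameters of one (bottle, time point) event table; events are
    re-drawn deterministically from ``event_seed`` on demand."""

    month: str
    treatment: str
    offset: float
    temperature_C: float
    ambient_temperature_C: float
    replicate: int
    time_d: float
    gain: float
    acquired_volume_mL: float
    clusters: tuple[ClusterSpec, ...]
    truth: dict
    event_seed: np.random.SeedSequence

    @property
    def key(self) -> tuple:
        return (self.month, self.treatment, self.offset, self.replicate, self.time_d)


class SyntheticExperiment:
    """Lazy container for one simulated year.

    Scalar-level randomness (monthly slope deviations, bottle effects,
    per-acquisition gains, jitters, event counts) is realized eagerly at
    construction; the event clouds themselves are re-generated
    deterministically per acquisition from stored seed substreams, keeping
    memory flat for the full 12-month x 18-bottle design.
    """

    def __init__(self, design: ExperimentDesign, truth: TruthParams, seed: int):
        self.design = design
        self.truth = truth
        self.seed = seed
        self.acquisitions: list[Acquisition] = []
        self.abundance: pd.DataFrame
        self.bottle_truth: pd.DataFrame
        self.monthly_truth: pd.DataFrame
        self.ground_truth: dict
        self._build()

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        design, truth = self.design, self.truth
        root = np.random.SeedSequence(self.seed)
        month_ss, _community_ss, bottle_root = root.spawn(3)
        month_rng = np.random.default_rng(month_ss)

        # month-level slope deviations, correlated between size and NAC
        rho = truth.slope_pair_correlation
        chol = np.array([[1.0, 0.0], [rho, np.sqrt(1 - rho**2)]])
        monthly = {}
        rows = []
        for month in design.months:
            for key, pop in truth.populations.items():
                z = chol @ month_rng.standard_normal(2)
                ds = pop.monthly_size_slope_sd * z[0]
                dn = pop.monthly_nac_slope_sd * z[1]
                monthly[(month, key)] = (
                    pop.size_slope_um3_per_degC + ds,
                    pop.nac_slope_fru_per_degC + dn,
                )
                rows.append(dict(
                    month=month, group=key[0], treatment=key[1],
                    size_slope_um3_per_degC=monthly[(month, key)][0],
                    nac_slope_fru_per_degC=monthly[(month, key)][1],
                ))
        self.monthly_truth = pd.DataFrame(rows)

        bottles = list(design.bottles())
        bottle_children = bottle_root.spawn(len(bottles))
        ab_rows, bt_rows = [], []
        for (month, treatment, offset, rep), child in zip(bottles, bottle_children):
            brng_ss, acq_root = child.spawn(2)
            brng = np.random.default_rng(brng_ss)
            t_amb = design.ambient_temperature_degC[month]
            temp = t_amb + offset
            effects = {}
            for group in GROUPS:
                pop = truth.populations[(group, treatment)]
                effects[group] = (
                    brng.normal(0.0, truth.bottle_sd_frac * pop.ambient_volume_um3),
                    brng.normal(0.0, truth.bottle_sd_frac * pop.ambient_nac_fru),
                )
                _, mu = abundance_at(0.0, pop.growth, temp, t_amb)
                bt_rows.append(dict(
                    month=month, treatment=treatment, temperature_offset=offset,
                    temperature_C=temp, replicate=rep, group=group,
                    bottle_volume_effect=effects[group][0],
                    bottle_nac_effect=effects[group][1],
                    mu_per_day=mu,
                ))
            acq_children = acq_root.spawn(len(design.sampling_times_days))
            for time_d, acq_child in zip(design.sampling_times_days, acq_children):
                acq = self._make_acquisition(
                    brng, acq_child, month, treatment, offset, rep,
                    time_d, temp, t_amb, monthly, effects,
                )
                self.acquisitions.append(acq)
                for group in GROUPS:
                    ab_rows.append(dict(
                        month=month, treatment=treatment,
                        temperature_offset=offset, temperature_C=temp,
                        replicate=rep, time_d=time_d, group=group,
                        true_abundance_per_mL=acq.truth["true_abundance"][group],
                        sampled_events=acq.truth["n_events"][group],
                        acquired_volume_mL=acq.acquired_volume_mL,
                    ))
        self.abundance = pd.DataFrame(ab_rows)
        self.bottle_truth = pd.DataFrame(bt_rows)
        self.ground_truth = self._ground_truth_record()

    def _make_acquisition(self, brng, acq_child, month, treatment, offset,
                          rep, time_d, temp, t_amb, monthly, effects) -> Acquisition:
        truth = self.truth
        gain = float(np.exp(brng.normal(0.0, truth.gain_sd))) if truth.gain_sd else 1.0
        n_noisy, targets = {}, {}
        for group in GROUPS:
            pop = truth.populations[(group, treatment)]
            n_det, mu = abundance_at(time_d, pop.growth, temp, t_amb)
            noise = (np.exp(brng.normal(0.0, np.sqrt(np.log1p(truth.abundance_cv**2))))
                     if truth.abundance_cv else 1.0)
            n_noisy[group] = float(n_det) * noise
            size_slope, nac_slope = monthly[(month, (group, treatment))]
            phase = _phase(time_d, pop.growth, mu)
            drift = {"lag": 1.0 + truth.lag_drift_frac,
                     "exponential": 1.0 - truth.growth_drift_frac,
                     "stationary": 1.0}[phase]
            dv, dn = effects[group]
            jv = (brng.normal(0.0, truth.time_sd_frac * pop.ambient_volume_um3)
                  if truth.time_sd_frac else 0.0)
            jn = (brng.normal(0.0, truth.time_sd_frac * pop.ambient_nac_fru)
                  if truth.time_sd_frac else 0.0)
            vol = (pop.ambient_volume_um3 + size_slope * (temp - t_amb)) * drift + dv + jv
            nac = (pop.ambient_nac_fru + nac_slope * (temp - t_amb)) * drift + dn + jn
            targets[group] = [
                max(vol, 0.05 * pop.ambient_volume_um3),
                max(nac, 0.05 * pop.ambient_nac_fru),
                phase,
            ]
        # Rare noisy draws can push the realized NAC locations together;
        # the HNA/LNA groups are *defined* by fluorescence separation, so
        # keep the HNA location at least 30% above the LNA one.
        if targets["HNA"][1] < 1.3 * targets["LNA"][1]:
            targets["HNA"][1] = 1.3 * targets["LNA"][1]

        total = sum(n_noisy.values())
        acq_vol = truth.n_target_events / total
        counts = {}
        for group in GROUPS:
            lam = n_noisy[group] * acq_vol
            counts[group] = int(brng.poisson(lam)) if truth.poisson_counts else int(round(lam))

        specs = []
        for group in GROUPS:
            pop = truth.populations[(group, treatment)]
            vol, nac, _ = targets[group]
            mean_ssc = mean_ssc_for_volume(vol, pop.ssc_log_sd, truth.calibration)
            specs.append(ClusterSpec(
                name=group, n=counts[group],
                mean_ssc=mean_ssc * truth.bead.ssc_raw,
                mean_gf=nac * truth.bead.gf_raw,
                ssc_log_sd=pop.ssc_log_sd, gf_log_sd=pop.gf_log_sd,
            ))
        if any(s.n > 0 for s in specs):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = solve_log_correlation(
                    [s for s in specs if s.n > 0], truth.size_nac_correlation,
                    truth.calibration,
                )
            specs = [replace(s, log_correlation=rho) for s in specs]

        return Acquisition(
            month=month, treatment=treatment, offset=offset,
            temperature_C=temp, ambient_temperature_C=t_amb, replicate=rep,
            time_d=time_d, gain=gain, acquired_volume_mL=acq_vol,
            clusters=tuple(specs),
            truth=dict(
                true_abundance={g: n_noisy[g] for g in GROUPS},
                n_events=dict(counts),
                target_mean_volume={g: targets[g][0] for g in GROUPS},
                target_mean_nac={g: targets[g][1] for g in GROUPS},
                phase={g: targets[g][2] for g in GROUPS},
            ),
            event_seed=acq_child,
        )

    # -- access ------------------------------------------------------------

    def events_for(self, acq: Acquisition) -> pd.DataFrame:
        """(Re)generate the event table of one acquisition; deterministic."""
        rng = np.random.default_rng(acq.event_seed)
        return generate_cytogram(acq.clusters, bead=self.truth.bead,
                                 seed=rng, gain=acq.gain)

    def iter_event_tables(self) -> Iterator[tuple[Acquisition, pd.DataFrame]]:
        for acq in self.acquisitions:
            yield acq, self.events_for(acq)

    def _ground_truth_record(self) -> dict:
        pops = {
            f"{g}/{t}": asdict(p) for (g, t), p in self.truth.populations.items()
        }
        return dict(
            seed=self.seed,
            design=dict(
                months=list(self.design.months),
                treatments=list(self.design.treatments),
                temperature_offsets_degC=list(self.design.temperature_offsets_degC),
                ambient_temperature_degC=dict(self.design.ambient_temperature_degC),
                replicates=self.design.replicates,
                sampling_times_days=list(self.design.sampling_times_days),
            ),
            truth=dict(
                populations=pops,
                size_nac_correlation=self.truth.size_nac_correlation,
                slope_pair_correlation=self.truth.slope_pair_correlation,
                bead=asdict(self.truth.bead),
                calibration=dict(
                    form=self.truth.calibration.form,
                    coefficients=list(self.truth.calibration.coefficients),
                ),
                n_target_events=self.truth.n_target_events,
                bottle_sd_frac=self.truth.bottle_sd_frac,
                time_sd_frac=self.truth.time_sd_frac,
                abundance_cv=self.truth.abundance_cv,
                gain_sd=self.truth.gain_sd,
                lag_drift_frac=self.truth.lag_drift_frac,
                growth_drift_frac=self.truth.growth_drift_frac,
            ),
            monthly_slopes=self.monthly_truth.to_dict(orient="records"),
        )

    def ground_truth_json(self) -> str:
        return json.dumps(self.ground_truth, indent=2, sort_keys=True)


def generate_experiment(design: ExperimentDesign, truth: TruthParams,
                        seed: int) -> SyntheticExperiment:
    """Simulate one full incubation year; see :class:`SyntheticExperiment`."""
    return SyntheticExperiment(design, truth, seed)


# ---------------------------------------------------------------------------
# Fast moment-level simulator (no events)
# ---------------------------------------------------------------------------


def simulate_bottle_summaries(
    design: ExperimentDesign,
    truth: TruthParams,
    seed: int,
) -> pd.DataFrame:
    """Per-bottle experiment means drawn directly at the summary level.

    Moment-level twin of :func:`generate_experiment`: the per-bottle mean
    volume/NAC is ambient + slope * (T - T_ambient) plus the bottle-level
    noise, skipping event sampling, phase drift and time jitter. Used for
    calibration studies (e.g. confidence-interval coverage over many
    replicate months) where event-level detail is irrelevant.
    """
    root = np.random.SeedSequence(seed)
    month_ss, _c, bottle_root = root.spawn(3)
    month_rng = np.random.default_rng(month_ss)
    rho = truth.slope_pair_correlation
    chol = np.array([[1.0, 0.0], [rho, np.sqrt(1 - rho**2)]])
    monthly = {}
    for month in design.months:
        for key, pop in truth.populations.items():
            z = chol @ month_rng.standard_normal(2)
            monthly[(month, key)] = (
                pop.size_slope_um3_per_degC + pop.monthly_size_slope_sd * z[0],
                pop.nac_slope_fru_per_degC + pop.monthly_nac_slope_sd * z[1],
            )
    bottles = list(design.bottles())
    children = bottle_root.spawn(len(bottles))
    rows = []
    for (month, treatment, offset, rep), child in zip(bottles, children):
        rng = np.random.default_rng(child)
        t_amb = design.ambient_temperature_degC[month]
        temp = t_amb + offset
        for group in GROUPS:
            pop = truth.populations[(group, treatment)]
            size_slope, nac_slope = monthly[(month, (group, treatment))]
            vol = (pop.ambient_volume_um3 + size_slope * (temp - t_amb)
                   + rng.normal(0.0, truth.bottle_sd_frac * pop.ambient_volume_um3))
            nac = (pop.ambient_nac_fru + nac_slope * (temp - t_amb)
                   + rng.normal(0.0, truth.bottle_sd_frac * pop.ambient_nac_fru))
            rows.append(dict(
                month=month, treatment=treatment, temperature_offset=offset,
                temperature_C=temp, replicate=rep, group=group,
                mean_volume_um3=vol, mean_nac_fru=nac,
                true_size_slope=size_slope, true_nac_slope=nac_slope,
                ambient_volume_um3=pop.ambient_volume_um3,
                ambient_nac_fru=pop.ambient_nac_fru,
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Community tables (CARD-FISH and ARISA)
# ---------------------------------------------------------------------------

PROBES = ("SAR11", "Rhodobacteraceae", "Gammaproteobacteria", "Bacteroidetes")


@dataclass(frozen=True)
class CommunityTruth:
    """Truth parameters for the community-composition generators.

    ``probe_proportions`` are fractions of DAPI-stained cells detected by
    each broad-taxon probe; the default four sum to 0.704 (the remainder is
    unclassified). ARISA communities carry 35 true fragments per month, of
    which ~8 are dominant enough to survive the downstream 0.09 relative-
    intensity cutoff; fragment lengths are jittered by a 0.4 bp measurement
    error so 3-bp binning is non-trivial.
    """

    probe_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "SAR11": 0.30, "Rhodobacteraceae": 0.12,
            "Gammaproteobacteria": 0.15, "Bacteroidetes": 0.134,
        }
    )
    month_variation_sd: float = 0.35
    sample_noise_sd: float = 0.05
    dapi_count: int = 800
    cardfish_replicates: int = 2
    arisa_n_fragments: int = 35
    arisa_n_dominant: int = 8
    arisa_alpha_dominant: float = 5.0
    arisa_alpha_rare: float = 0.2
    arisa_length_range: tuple[float, float] = (120.0, 950.0)
    arisa_length_jitter_sd: float = 0.4
    arisa_sample_intensity_sd: float = 0.15
    arisa_out_of_range_peaks: int = 2
    arisa_raw_scale: float = 1000.0
    outlier_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        props = dict(self.probe_proportions)
        if any(p < 0 for p in props.values()):
            raise ValueError("probe proportions must be >= 0")
        if sum(props.values()) > 1.0 + 1e-12:
            raise ValueError("probe proportions must sum to <= 1")


def default_community_truth() -> CommunityTruth:
    return CommunityTruth()


def _sample_id(month: str, treatment: str, offset: float, rep: int | None = None) -> str:
    tag = "is" if offset == 0 else ("+" if offset > 0 else "-")
    base = f"{month}-{treatment}-{tag}"
    return base if rep is None else f"{base}-r{rep}"


def generate_community_tables(
    design: ExperimentDesign,
    truth: CommunityTruth,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic CARD-FISH count table and ARISA peak table.

    One community is drawn per (month, treatment); all three temperature
    treatments of that cell share it up to small sample-level noise, so
    same-month samples should cluster together downstream. Samples named in
    ``truth.outlier_samples`` instead get an independent community (planted
    outliers). CARD-FISH counts are multinomial draws around the
    proportions; ARISA peaks carry length jitter, raw (unnormalized)
    intensities, and a few out-of-range peaks to exercise the filters.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    base = np.array([truth.probe_proportions[p] for p in PROBES])
    base_sum = base.sum()

    card_rows, arisa_rows = [], []
    for month in design.months:
        for treatment in design.treatments:
            # month x treatment community (CARD-FISH proportions)
            p_month = base * np.exp(rng.normal(0.0, truth.month_variation_sd, base.size))
            p_month *= base_sum / p_month.sum()
            # month x treatment ARISA source profile
            lo, hi = truth.arisa_length_range
            lengths = np.sort(rng.uniform(lo, hi, truth.arisa_n_fragments))
            alphas = np.full(truth.arisa_n_fragments, truth.arisa_alpha_rare)
            dom = rng.choice(truth.arisa_n_fragments, truth.arisa_n_dominant,
                             replace=False)
            alphas[dom] = truth.arisa_alpha_dominant
            intensities = rng.dirichlet(alphas)

            for offset in design.temperature_offsets_degC:
                # CARD-FISH: two replicate bottles counted per treatment cell
                for rep in range(1, truth.cardfish_replicates + 1):
                    sid = _sample_id(month, treatment, offset, rep)
                    p = p_month * np.exp(rng.normal(0.0, truth.sample_noise_sd, base.size))
                    if p.sum() > 0.98:  # keep an unclassified remainder
                        p *= 0.98 / p.sum()
                    probs = np.append(p, 1.0 - p.sum())
                    counts = rng.multinomial(truth.dapi_count, probs)
                    card_rows.append(dict(
                        sample=sid, month=month, treatment=treatment,
                        temperature_offset=offset, replicate=rep,
                        **{probe: int(c) for probe, c in zip(PROBES, counts[:-1])},
                        dapi_total=truth.dapi_count,
                    ))
                # ARISA: one bottle per treatment cell
                sid = _sample_id(month, treatment, offset)
                if sid in truth.outlier_samples:
                    lens = np.sort(rng.uniform(lo, hi, truth.arisa_n_fragments))
                    al = np.full(truth.arisa_n_fragments, truth.arisa_alpha_rare)
                    d2 = rng.choice(truth.arisa_n_fragments, truth.arisa_n_dominant,
                                    replace=False)
                    al[d2] = truth.arisa_alpha_dominant
                    inten = rng.dirichlet(al)
                    src_len, src_int, src_otu = lens, inten, -1 - np.arange(lens.size)
                else:
                    src_len, src_int = lengths, intensities
                    src_otu = np.arange(lengths.size)
                jitter = rng.normal(0.0, truth.arisa_length_jitter_sd, src_len.size)
                noise = np.exp(rng.normal(0.0, truth.arisa_sample_intensity_sd,
                                          src_int.size))
                obs_len = src_len + jitter
                obs_rfi = src_int * noise * truth.arisa_raw_scale
                for L, r, o in zip(obs_len, obs_rfi, src_otu):
                    arisa_rows.append(dict(sample=sid, month=month,
                                           treatment=treatment,
                                           temperature_offset=offset,
                                           fragment_bp=float(L), rfi=float(r),
                                           true_otu=int(o)))
                for _ in range(truth.arisa_out_of_range_peaks):
                    L = rng.uniform(40.0, 95.0) if rng.random() < 0.5 else rng.uniform(
                        1005.0, 1200.0)
                    arisa_rows.append(dict(sample=sid, month=month,
                                           treatment=treatment,
                                           temperature_offset=offset,
                                           fragment_bp=float(L),
                                           rfi=float(rng.uniform(0.05, 0.3)
                                                     * truth.arisa_raw_scale),
                                           true_otu=-999))
    return pd.DataFrame(card_rows), pd.DataFrame(arisa_rows)
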