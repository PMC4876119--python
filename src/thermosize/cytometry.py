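"""Flow-cytometry processing for heterotrophic bacterioplankton.

Turns per-event optical signal tables (side scatter ``ssc`` and green
fluorescence ``gf`` after nucleic-acid staining) into per-acquisition,
per-population summaries:

* internal-standard normalization against 1 um reference beads, yielding
  bead-relative units (``ru`` for scatter, ``fru`` for fluorescence);
* automatic separation of the two canonical bacterial populations of high
  and low nucleic acid content (HNA / LNA) by a threshold on log green
  fluorescence;
* conversion of bead-relative scatter to cell diameter through an empirical
  calibration model and to volume assuming spherical cells;
* inter-calibration between nucleic-acid dyes (Syto 13 vs Sybr-Green I)
  fitted by ordinary least squares on paired samples.

Event tables are plain :class:`pandas.DataFrame` objects with columns
``ssc`` and ``gf`` (raw instrument units) or ``ssc_ru`` / ``gf_fru``
(bead-relative units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .constants import SPHERE_FACTOR

__all__ = [
    "CalibrationModel",
    "BeadCountError",
    "GateResult",
    "default_size_calibration",
    "gate_populations",
    "normalize_to_beads",
    "ssc_to_diameter",
    "diameter_to_volume",
    "volume_to_diameter",
    "fit_dye_calibration",
    "syto_to_sybr",
    "population_stats",
]

BACTERIAL_GROUPS = ("LNA", "HNA")


class BeadCountError(ValueError):
    """Raised when an acquisition contains too few bead events to normalize."""


@dataclass(frozen=True)
class CalibrationModel:
    """A strictly monotone-increasing calibration curve.

    Parameters
    ----------
    kind:
        ``"ssc_to_diameter"`` or ``"syto_to_sybr"``.
    form:
        ``"power"`` (``y = a * x**b``) or ``"linear"`` (``y = a + b * x``).
    coefficients:
        ``(a, b)`` for either form.
    valid_range:
        Input range ``(lo, hi)`` the model was fitted on; evaluation outside
        it is allowed but flagged as extrapolation. ``None`` disables the
        check.
    """

    kind: str
    form: str
    coefficients: tuple[float, float]
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("power", "linear"):
            raise ValueError(f"unknown calibration form {self.form!r}")
        a, b = self.coefficients
        if self.form == "power" and (a <= 0 or b <= 0):
            raise ValueError("power calibration requires a > 0 and b > 0 (monotone)")
        if self.form == "linear" and b <= 0:
            raise ValueError("linear calibration requires positive slope (monotone)")
        if self.valid_range is not None and self.valid_range[0] >= self.valid_range[1]:
            raise ValueError("valid_range must be (lo, hi) with lo < hi")

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        a, b = self.coefficients
        if self.form == "power":
            return a * np.power(x, b)
        return a + b * x

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        a, b = self.coefficients
        if self.form == "power":
            return np.power(y / a, 1.0 / b)
        return (y - a) / b

    def extrapolated(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.valid_range is None:
            return np.zeros(x.shape, dtype=bool)
        lo, hi = self.valid_range
        return (x < lo) | (x > hi)


def default_size_calibration() -> CalibrationModel:
    """Default scatter-to-diameter model, ``d = ssc_ru ** 0.5`` (um).

    The power law maps the bead position (1 ru, 1 um beads) to 1 um and
    places ambient bacterial volumes in the 0.035-0.091 um^3 range for
    bead-relative scatter near 0.2.
    """
    return CalibrationModel(
        kind="ssc_to_diameter",
        form="power",
        coefficients=(1.0, 0.5),
        valid_range=(0.01, 4.0),
    )


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------


@dataclass
class GateResult:
    """Per-event population labels plus the gate parameters used.

    ``labels`` take values ``"bead"``, ``"LNA"``, ``"HNA"`` or
    ``"unassigned"`` (the latter only when the fluorescence distribution of
    the non-bead events is unimodal and no HNA/LNA split is defensible).
    """

    labels: np.ndarray
    threshold_log_gf: float | None
    unimodal: bool
    bead_position: tuple[float, float] | None
    counts: dict = field(default_factory=dict)
    method: str = "kde-minimum"

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1e-3)
    return 0.9 * scale * n ** (-1 / 5)


def _smoothed_density(x: np.ndarray, grid_points: int = 512):
    bw = _silverman_bandwidth(x)
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    counts, edges = np.histogram(x, bins=grid_points, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    binwidth = edges[1] - edges[0]
    dens = gaussian_filter1d(counts.astype(float), sigma=max(bw / binwidth, 1.0))
    return centers, dens


def _gmm_threshold(x: np.ndarray) -> float | None:
    """Two-component Gaussian-mixture fallback; None if not clearly bimodal."""
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, random_state=0, n_init=1)
    gm.fit(x.reshape(-1, 1))
    mus = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mus)
    mus, sds = mus[order], sds[order]
    if (mus[1] - mus[0]) < 2.0 * np.sqrt(np.mean(sds**2)):
        return None
    grid = np.linspace(mus[0], mus[1], 512)
    resp = gm.predict_proba(grid.reshape(-1, 1))[:, order]
    cross = np.nonzero(np.diff(np.sign(resp[:, 1] - resp[:, 0])))[0]
    if cross.size == 0:
        return float(0.5 * (mus[0] + mus[1]))
    return float(grid[cross[0]])


def gate_populations(
    events: pd.DataFrame,
    bead_position: tuple[float, float] | None = None,
    bead_log_window: float = 0.4,
    min_prominence: float = 0.05,
) -> GateResult:
    """Label events as bead / LNA / HNA.

    Beads are identified first as the events closest (within
    ``bead_log_window`` in natural-log units, both channels) to the known
    nominal bead position, which must be given in the same units as the
    event table. The remaining events are split on log green fluorescence at
    the minimum of a smoothed density estimate between the two highest
    modes; a two-component Gaussian mixture is tried when the density is
    unimodal. If no defensible split exists the result is flagged
    ``unimodal`` and the non-bead events are labelled ``"unassigned"``.
    """
    ssc, gf = _signal_columns(events)
    if np.any(ssc <= 0) or np.any(gf <= 0):
        raise ValueError("signals must be positive (log-transformable)")
    n = len(events)
    labels = np.full(n, "unassigned", dtype=object)

    bead_mask = np.zeros(n, dtype=bool)
    if bead_position is not None:
        bs, bg = bead_position
        bead_mask = (np.abs(np.log(ssc / bs)) < bead_log_window) & (
            np.abs(np.log(gf / bg)) < bead_log_window
        )
        labels[bead_mask] = "bead"

    bact = ~bead_mask
    lx = np.log(gf[bact])
    counts: dict = {"bead": int(bead_mask.sum())}
    if lx.size == 0:
        return GateResult(labels, None, False, bead_position, counts)

    threshold = None
    method = "kde-minimum"
    if np.ptp(lx) > 0:
        centers, dens = _smoothed_density(lx)
        peaks, props = find_peaks(dens, prominence=min_prominence * dens.max())
        if peaks.size >= 2:
            top = peaks[np.argsort(dens[peaks])[-2:]]
            left, right = np.sort(top)
            valley = left + int(np.argmin(dens[left : right + 1]))
            threshold = float(centers[valley])
        elif lx.size >= 10:
            threshold = _gmm_threshold(lx)
            method = "gmm-fallback"

    if threshold is None:
        warnings.warn(
            "unimodal green-fluorescence distribution: no HNA/LNA split",
            stacklevel=2,
        )
        counts["unassigned"] = int(bact.sum())
        return GateResult(labels, None, True, bead_position, counts, method)

    lna = bact & (np.log(gf) < threshold)
    hna = bact & ~lna
    labels[lna] = "LNA"
    labels[hna] = "HNA"
    counts["LNA"] = int(lna.sum())
    counts["HNA"] = int(hna.sum())
    return GateResult(labels, threshold, False, bead_position, counts, method)


def _signal_columns(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if {"ssc", "gf"} <= set(events.columns):
        return events["ssc"].to_numpy(float), events["gf"].to_numpy(float)
    if {"ssc_ru", "gf_fru"} <= set(events.columns):
        return events["ssc_ru"].to_numpy(float), events["gf_fru"].to_numpy(float)
    raise KeyError("event table needs columns (ssc, gf) or (ssc_ru, gf_fru)")


# ---------------------------------------------------------------------------
# Bead normalization
# ---------------------------------------------------------------------------


def normalize_to_beads(
    events: pd.DataFrame,
    gates: GateResult,
    min_beads: int = 20,
    acquisition_id: str | None = None,
) -> pd.DataFrame:
    """Divide both channels by the arithmetic mean of the bead events.

    The bead mean maps to exactly 1.0 ru/fru, making the output invariant to
    any common instrument-gain rescaling. Raises :class:`BeadCountError`
    (naming the acquisition) when fewer than ``min_beads`` bead events are
    present.
    """
    ssc, gf = _signal_columns(events)
    beads = gates.mask("bead")
    if beads.sum() < min_beads:
        where = f" in acquisition {acquisition_id!r}" if acquisition_id else ""
        raise BeadCountError(
            f"only {int(beads.sum())} bead events{where}; need >= {min_beads}"
        )
    out = events.copy()
    out["ssc_ru"] = ssc / ssc[beads].mean()
    out["gf_fru"] = gf / gf[beads].mean()
    return out


# ---------------------------------------------------------------------------
# Size conversion
# ---------------------------------------------------------------------------


def ssc_to_diameter(ssc_ru, model: CalibrationModel):
    """Map bead-relative scatter to cell diameter (um).

    Returns ``(diameter, extrapolated)`` where ``extrapolated`` flags inputs
    outside the model's valid range (values are still returned).
    """
    if model.kind != "ssc_to_diameter":
        raise ValueError(f"expected an ssc_to_diameter model, got {model.kind!r}")
    return model.evaluate(ssc_ru), model.extrapolated(ssc_ru)


def diameter_to_volume(d):
    """Spherical cell volume, ``V = (pi/6) d^3`` (um^3)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    return SPHERE_FACTOR * d**3


def volume_to_diameter(v):
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    return np.cbrt(v / SPHERE_FACTOR)


# ---------------------------------------------------------------------------
# Dye inter-calibration
# ---------------------------------------------------------------------------


def fit_dye_calibration(gf_syto, gf_sybr) -> CalibrationModel:
    """OLS fit of Sybr-Green I fluorescence on paired Syto 13 fluorescence.

    Used to place measurements made with different nucleic-acid stains on a
    common (Sybr-Green I) scale. Returns a linear
    :class:`CalibrationModel`; the fitted r^2 and coefficient standard
    errors are attached as ``model.fit_stats``.
    """
    import statsmodels.api as sm

    x = np.asarray(gf_syto, dtype=float)
    y = np.asarray(gf_sybr, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    model = CalibrationModel(
        kind="syto_to_sybr",
        form="linear",
        coefficients=(float(res.params[0]), float(res.params[1])),
        valid_range=(float(x.min()), float(x.max())),
    )
    object.__setattr__(
        model,
        "fit_stats",
        {"r_squared": float(res.rsquared), "bse": tuple(map(float, res.bse)), "n": int(x.size)},
    )
    return model


def syto_to_sybr(gf_syto, model: CalibrationModel | None):
    """Convert Syto 13 fluorescence to the Sybr-Green I scale."""
    if model is None:
        raise ValueError("no dye calibration model available")
    if model.kind != "syto_to_sybr":
        raise ValueError(f"expected a syto_to_sybr model, got {model.kind!r}")
    return model.evaluate(gf_syto)


# ---------------------------------------------------------------------------
# Population summaries
# ---------------------------------------------------------------------------


def population_stats(
    events: pd.DataFrame,
    gates: GateResult,
    calibration: CalibrationModel,
    acquired_volume_mL: float,
    groups: Sequence[str] = BACTERIAL_GROUPS,
) -> pd.DataFrame:
    """Per-group abundance and mean signal/size summaries.

    Abundance is labelled-event count divided by the acquired volume. Mean
    cell volume is the average over events of V(d(ssc_ru)) — conversion is
    applied per event and then averaged, because the biological quantity of
    interest is the mean cell volume, not the volume of the mean-scatter
    cell (the two differ by a Jensen gap for dispersed populations).

    Empty gates yield abundance 0, NaN means, and ``empty = True``.
    """
    if acquired_volume_mL <= 0:
        raise ValueError("acquired volume must be positive")
    if "ssc_ru" not in events.columns or "gf_fru" not in events.columns:
        raise ValueError("events must be bead-normalized first (ssc_ru/gf_fru)")
    ssc = events["ssc_ru"].to_numpy(float)
    gf = events["gf_fru"].to_numpy(float)
    rows = []
    for group in groups:
        m = gates.mask(group)
        n = int(m.sum())
        if n == 0:
            rows.append(
                dict(
                    group=group, n_events=0, abundance_per_mL=0.0,
                    mean_ssc_ru=np.nan, mean_gf_fru=np.nan,
                    mean_diameter_um=np.nan, mean_volume_um3=np.nan,
                    frac_extrapolated=np.nan, empty=True,
                )
            )
            continue
        diam, extrap = ssc_to_diameter(ssc[m], calibration)
        vol = diameter_to_volume(diam)
        rows.append(
            dict(
                group=group,
                n_events=n,
                abundance_per_mL=n / acquired_volume_mL,
                mean_ssc_ru=float(ssc[m].mean()),
                mean_gf_fru=float(gf[m].mean()),
                mean_diameter_um=float(diam.mean()),
                mean_volume_um3=float(vol.mean()),
                frac_extrapolated=float(extrap.mean()),
                empty=False,
            )
        )
    return pd.DataFrame(rows)
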