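"""Batch-vial headspace gas kinetics and biokinetic parameter estimation.

Turns raw headspace gas time series from stirred batch incubations into
biological production/consumption rates (corrected for the dilution caused
by gas sampling and for first-order leakage), dissolved gas concentrations,
cell-number trajectories, cell-specific rates, and fitted biokinetic
parameters (mu_max, V_max, K_m, growth yields, O2-onset thresholds).

Conventions
-----------
* times in hours, headspace amounts in mol per vial, dissolved
  concentrations in uM, cell-specific rates in fmol cell-1 h-1;
* rates are signed: positive = production, negative = consumption;
* ``RateSeries.cumulative`` is the running integral of the signed rate, so
  the cumulated *consumption* of a gas (cumO2, cumN2O) is its negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import (
    ATM_PA,
    ELECTRONS_PER_MOL,
    henry_coefficient,
    water_vapour_pressure_atm,
)

__all__ = [
    "VialSpec",
    "GasSeries",
    "RateSeries",
    "DissolvedSeries",
    "CellTrajectory",
    "BiokineticParams",
    "interval_rates",
    "liquid_corrected_rates",
    "dissolved_concentration",
    "henry_equilibrium",
    "aqueous_from_ppmv",
    "cell_trajectory",
    "specific_rates",
    "fit_growth_rate",
    "fit_michaelis_menten",
    "electron_flow",
    "growth_yield",
    "o2_onset_threshold",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VialSpec:
    """Physical description of one incubation vial.

    Defaults describe the stirred 120-ml serum vials with 50 ml culture used
    for respiratory phenotyping; ``kla`` and ``leak_coefficient`` may be a
    single float (all gases) or a per-gas mapping.
    """

    liquid_volume_ml: float = 50.0
    headspace_volume_ml: float = 70.0
    temperature_c: float = 23.0
    pressure_pa: float = ATM_PA
    kla: float | dict = 15.0                 # h-1, gas-liquid transfer
    sample_volume_ml: float = 1.0            # headspace removed per sampling
    replacement_gas: str = "He"
    leak_coefficient: float | dict = 0.0     # h-1, exchange with ambient
    ambient_amount_mol: dict = field(default_factory=dict)  # per gas

    def __post_init__(self) -> None:
        if self.liquid_volume_ml <= 0 or self.headspace_volume_ml <= 0:
            raise ValueError("vial volumes must be positive")
        if not 0 <= self.sample_volume_ml < self.headspace_volume_ml:
            raise ValueError("sample_volume_ml must be in [0, headspace_volume_ml)")
        for name in ("kla", "leak_coefficient"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError(f"{name} must be >= 0")

    def kla_for(self, gas: str) -> float:
        return self.kla[gas] if isinstance(self.kla, dict) else self.kla

    def leak_for(self, gas: str) -> float:
        lc = self.leak_coefficient
        return lc[gas] if isinstance(lc, dict) else lc

    @property
    def sampling_fraction(self) -> float:
        """Fraction of the headspace removed (and replaced) per sampling."""
        return self.sample_volume_ml / self.headspace_volume_ml


@dataclass
class GasSeries:
    """Time-stamped headspace amounts of one gas in one vial."""

    gas: str
    times_h: np.ndarray
    amount_mol: np.ndarray
    sampling_events_h: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.amount_mol = np.asarray(self.amount_mol, dtype=float)
        self.sampling_events_h = np.asarray(self.sampling_events_h, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.size != self.amount_mol.size:
            raise ValueError("times and amounts must be 1-d arrays of equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.amount_mol < 0):
            raise ValueError("headspace amounts must be >= 0")
        for t in self.sampling_events_h:
            if not np.any(np.isclose(self.times_h, t)):
                raise ValueError(
                    f"sampling event at t={t} h has no coinciding measurement"
                )


@dataclass
class RateSeries:
    """Per-interval biological rates and their running integral."""

    gas: str
    interval_midpoints_h: np.ndarray
    rate_mol_h: np.ndarray           # signed: production > 0
    interval_edges_h: np.ndarray     # len = n_intervals + 1
    cumulative_mol: np.ndarray       # at interval edges, starts at 0

    @property
    def cumulative_consumption_mol(self) -> np.ndarray:
        return -self.cumulative_mol

    def consumption_at(self, times_h: np.ndarray) -> np.ndarray:
        """Cumulated consumption interpolated onto arbitrary times."""
        return np.interp(times_h, self.interval_edges_h, -self.cumulative_mol)


@dataclass
class DissolvedSeries:
    gas: str
    times_h: np.ndarray
    concentration_um: np.ndarray


@dataclass
class CellTrajectory:
    times_h: np.ndarray
    n_cells: np.ndarray
    n_ini: float
    y_o2: float
    y_n2o: float

    def at(self, times_h: np.ndarray) -> np.ndarray:
        return np.interp(times_h, self.times_h, self.n_cells)


@dataclass
class BiokineticParams:
    """Fitted respiratory parameters of an N2O-respiring strain."""

    mu_max_o2: float | None = None          # h-1
    mu_max_n2o: float | None = None         # h-1
    v_max_o2: float | None = None           # fmol O2 cell-1 h-1
    v_max_n2o: float | None = None          # fmol N2O cell-1 h-1
    k_m_o2: float | None = None             # uM
    k_m_n2o: float | None = None            # uM
    y_o2: float | None = None               # cells mol-1
    y_n2o: float | None = None              # cells mol-1
    y_e_o2: float | None = None             # g CDW per mol e-
    y_e_n2o: float | None = None            # g CDW per mol e-
    cell_dry_weight_fg: float | None = None
    o2_onset_naive_um: float | None = None
    o2_onset_primed_um: float | None = None


# ---------------------------------------------------------------------------
# rate correction
# ---------------------------------------------------------------------------

def interval_rates(series: GasSeries, vial: VialSpec) -> RateSeries:
    """Biological production/consumption rates per measurement interval.

    Each sampling event removes ``sample_volume/headspace_volume`` of every
    headspace gas (replaced by inert gas) immediately *after* the reading at
    that time. Leakage is first-order exchange toward the ambient amount:
    within an interval with constant biological rate ``r``,

        dA/dt = r - lam * (A - A_amb),

    which is solved in closed form for ``r`` given the start (post-sampling)
    and end amounts.
    """
    if series.times_h.size < 2:
        raise ValueError("need at least two time points")
    t = series.times_h
    a = series.amount_mol
    lam = vial.leak_for(series.gas)
    a_amb = vial.ambient_amount_mol.get(series.gas, 0.0)
    f = vial.sampling_fraction
    is_event = np.isclose(t[:, None], series.sampling_events_h[None, :]).any(axis=1) \
        if series.sampling_events_h.size else np.zeros(t.size, dtype=bool)

    rates = np.empty(t.size - 1)
    for i in range(t.size - 1):
        a_start = a[i] * (1.0 - f) if is_event[i] else a[i]
        dt = t[i + 1] - t[i]
        if lam > 0:
            decay = np.exp(-lam * dt)
            rates[i] = (a[i + 1] - a_amb - (a_start - a_amb) * decay) * lam / (1.0 - decay)
        else:
            rates[i] = (a[i + 1] - a_start) / dt
    cumulative = np.concatenate([[0.0], np.cumsum(rates * np.diff(t))])
    return RateSeries(
        gas=series.gas,
        interval_midpoints_h=0.5 * (t[:-1] + t[1:]),
        rate_mol_h=rates,
        interval_edges_h=t.copy(),
        cumulative_mol=cumulative,
    )


def liquid_corrected_rates(series: GasSeries, vial: VialSpec,
                           rates: RateSeries | None = None,
                           initial_equilibrium: bool = True) -> RateSeries:
    """Biological rates including the change of the dissolved-gas inventory.

    Headspace differences alone understate biological consumption while the
    liquid inventory is being drawn down (N2O is soluble enough that the
    liquid of a half-full vial holds ~30% of the total). The correction
    estimates the dissolved concentration at each measurement time from the
    quasi-steady-state transfer balance and adds the inventory change to
    each interval:  r_bio = r_headspace + d(inventory)/dt.
    """
    if rates is None:
        rates = interval_rates(series, vial)
    kla = vial.kla_for(series.gas)
    v_liq_l = vial.liquid_volume_ml * 1e-3
    t = series.times_h
    from .constants import ppmv_from_mol_per_vial
    ppmv = ppmv_from_mol_per_vial(series.amount_mol, vial.headspace_volume_ml,
                                  vial.temperature_c, vial.pressure_pa)
    c_eq = aqueous_from_ppmv(ppmv, series.gas, vial.temperature_c,
                             vial.pressure_pa)                      # uM at edges
    # consumption rate at edges: mean of adjacent intervals, one-sided at ends;
    # a freshly prepared vial starts at equilibrium (no consumption yet)
    r_cons = np.clip(-rates.rate_mol_h, 0.0, None)
    r_first = 0.0 if initial_equilibrium else r_cons[0]
    r_edge = np.concatenate([[r_first],
                             0.5 * (r_cons[:-1] + r_cons[1:]),
                             [r_cons[-1]]])
    c_liq = c_eq - (r_edge / (kla * v_liq_l) * 1e6 if kla > 0 else 0.0)
    c_liq = np.clip(c_liq, 0.0, None)
    inventory = c_liq * 1e-6 * v_liq_l                              # mol
    corrected = rates.rate_mol_h + np.diff(inventory) / np.diff(t)
    cumulative = np.concatenate([[0.0], np.cumsum(corrected * np.diff(t))])
    return RateSeries(gas=series.gas,
                      interval_midpoints_h=rates.interval_midpoints_h,
                      rate_mol_h=corrected, interval_edges_h=t.copy(),
                      cumulative_mol=cumulative)


# ---------------------------------------------------------------------------
# dissolved concentrations and Henry equilibria
# ---------------------------------------------------------------------------

def henry_equilibrium(c_aq_um, gas: str, temperature_c: float,
                      pressure_pa: float = ATM_PA):
    """Equilibrium gas-phase mixing ratio (ppmv) for a dissolved concentration.

    The mixing ratio refers to the dry gas in a water-saturated headspace at
    the given total pressure (Weiss & Price 1980 convention).
    """
    k0 = henry_coefficient(gas, temperature_c)          # mol l-1 atm-1
    p_dry_atm = pressure_pa / ATM_PA - water_vapour_pressure_atm(temperature_c)
    return np.asarray(c_aq_um, dtype=float) * 1e-6 / (k0 * p_dry_atm) * 1e6


def aqueous_from_ppmv(ppmv, gas: str, temperature_c: float,
                      pressure_pa: float = ATM_PA):
    """Exact inverse of :func:`henry_equilibrium`: ppmv -> uM."""
    k0 = henry_coefficient(gas, temperature_c)
    p_dry_atm = pressure_pa / ATM_PA - water_vapour_pressure_atm(temperature_c)
    return np.asarray(ppmv, dtype=float) * 1e-6 * k0 * p_dry_atm * 1e6


def dissolved_concentration(series: GasSeries, vial: VialSpec,
                            sink_rate: RateSeries) -> DissolvedSeries:
    """Quasi-steady-state dissolved concentration from headspace + sink rate.

    At steady state the gas-liquid transfer balances the liquid-phase
    consumption: ``C_liq = C_eq - r / (kla * V_liq)`` with ``r`` the
    consumption rate (mol h-1, positive) and C_eq the Henry-law equilibrium
    for the concurrent headspace partial pressure. Evaluated at interval
    midpoints; negative values are clamped to zero with a warning.
    """
    kla = vial.kla_for(series.gas)
    from .constants import ppmv_from_mol_per_vial

    # consumption (positive) per interval; production intervals have no sink
    r_cons = np.clip(-sink_rate.rate_mol_h, 0.0, None)
    if kla == 0.0:
        if np.any(r_cons > 0):
            raise ValueError("kla = 0 with nonzero consumption: C_liq undefined")
        r_term_um = np.zeros_like(r_cons)
    else:
        r_term_um = r_cons / (kla * vial.liquid_volume_ml * 1e-3) * 1e6

    mid = sink_rate.interval_midpoints_h
    amount_mid = np.interp(mid, series.times_h, series.amount_mol)
    ppmv = ppmv_from_mol_per_vial(
        amount_mid, vial.headspace_volume_ml, vial.temperature_c, vial.pressure_pa
    )
    c_eq = aqueous_from_ppmv(ppmv, series.gas, vial.temperature_c, vial.pressure_pa)
    c_liq = c_eq - r_term_um
    if np.any(c_liq < 0):
        warnings.warn(
            f"{series.gas}: {int((c_liq < 0).sum())} dissolved concentrations "
            "below 0 clamped to 0 (consumption faster than transfer)",
            stacklevel=2,
        )
        c_liq = np.clip(c_liq, 0.0, None)
    return DissolvedSeries(gas=series.gas, times_h=mid, concentration_um=c_liq)


# ---------------------------------------------------------------------------
# cells and specific rates
# ---------------------------------------------------------------------------

def cell_trajectory(n_ini: float, y_o2: float, y_n2o: float,
                    o2_rates: RateSeries, n2o_rates: RateSeries | None = None
                    ) -> CellTrajectory:
    """Cells per vial: N(t) = N_ini + Y_O2*cumO2(t) + Y_N2O*cumN2O(t).

    cumO2 and cumN2O are the cumulated consumptions of the two gases.
    """
    if y_o2 < 0 or y_n2o < 0:
        raise ValueError("growth yields must be non-negative")
    times = o2_rates.interval_edges_h
    cum_o2 = np.clip(o2_rates.cumulative_consumption_mol, 0.0, None)
    cum_n2o = (np.clip(n2o_rates.consumption_at(times), 0.0, None)
               if n2o_rates is not None else np.zeros_like(times))
    n_cells = n_ini + y_o2 * cum_o2 + y_n2o * cum_n2o
    return CellTrajectory(times_h=times, n_cells=n_cells,
                          n_ini=n_ini, y_o2=y_o2, y_n2o=y_n2o)


def specific_rates(rates: RateSeries, traj: CellTrajectory) -> np.ndarray:
    """Cell-specific rates, fmol cell-1 h-1, at the interval midpoints.

    Divides each interval rate by the interval-mean cell number (trajectory
    interpolated to the interval edges). Signed like the input rates.
    """
    edges = rates.interval_edges_h
    cells_edges = traj.at(edges)
    cells_mean = 0.5 * (cells_edges[:-1] + cells_edges[1:])
    if np.any(cells_mean <= 0):
        raise ValueError("cell number must be positive to form specific rates")
    return rates.rate_mol_h / cells_mean * 1e15


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class GrowthRateFit:
    mu: float            # h-1
    r0: float            # mol h-1 at window start
    se_mu: float
    se_r0: float
    window_h: tuple


def _auto_window(t: np.ndarray, log_r: np.ndarray, r2_min: float) -> slice:
    """Longest span where log-rate is linear (R^2 >= r2_min); earliest wins ties."""
    n = t.size
    best = None
    for length in range(n, 3, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            res = stats.linregress(t[sl], log_r[sl])
            if res.rvalue**2 >= r2_min:
                best = sl
                break
        if best is not None:
            break
    if best is None:
        best = slice(0, n)
    return best


def fit_growth_rate(rates: RateSeries, window_h: tuple | None = None,
                    r2_min: float = 0.98) -> GrowthRateFit:
    """Exponential fit r(t) = r0 * exp(mu t) to consumption magnitudes.

    Rates during unrestricted growth increase exponentially with the
    maximum specific growth rate; ``mu`` therefore estimates mu_max. The
    fit is nonlinear least squares on the rates themselves (not log-rates),
    started from the log-linear regression.
    """
    t = rates.interval_midpoints_h
    r = np.abs(rates.rate_mol_h)
    if window_h is not None:
        mask = (t >= window_h[0]) & (t <= window_h[1])
        t, r = t[mask], r[mask]
    if t.size < 4:
        raise ValueError("need >= 4 points of unrestricted respiration")
    if np.any(r <= 0):
        raise ValueError("non-positive rates in fitting window")
    log_r = np.log(r)
    if window_h is None:
        sl = _auto_window(t, log_r, r2_min)
        t, r, log_r = t[sl], r[sl], log_r[sl]
    lin = stats.linregress(t, log_r)
    t0 = t[0]
    p0 = (lin.slope, np.exp(lin.intercept + lin.slope * t0))
    popt, pcov = optimize.curve_fit(
        lambda tt, mu, r0: r0 * np.exp(mu * (tt - t0)), t, r, p0=p0,
        maxfev=10000, xtol=1e-12, ftol=1e-12,
    )
    se = np.sqrt(np.diag(pcov))
    return GrowthRateFit(mu=popt[0], r0=popt[1], se_mu=se[0], se_r0=se[1],
                         window_h=(float(t[0]), float(t[-1])))


@dataclass
class MichaelisMentenFit:
    v_max: float
    k_m: float
    se_v_max: float
    se_k_m: float
    at_boundary: bool = False       # flat data: K_m -> 0 saturation limit


def fit_michaelis_menten(v, c, v_max0: float | None = None,
                         k_m0: float | None = None) -> MichaelisMentenFit:
    """Least-squares fit of v = V_max * C / (K_m + C).

    ``v`` are specific rates (consumption magnitudes) and ``c`` the matching
    dissolved concentrations (uM). Start values default to V_max = max(v)
    and K_m = concentration at half-max. Flat data (no curvature) yield a
    boundary result with K_m ~ 0 flagged rather than an exception, unless
    there are too few points.
    """
    v = np.abs(np.asarray(v, dtype=float))
    c = np.asarray(c, dtype=float)
    if v.size != c.size:
        raise ValueError("v and c must have equal length")
    if v.size < 4:
        raise ValueError("need >= 4 (rate, concentration) points")
    if np.ptp(c) == 0:
        raise ValueError("concentrations show no spread; cannot fit K_m")

    if v_max0 is None:
        v_max0 = float(np.max(v))
    if k_m0 is None:
        half = 0.5 * np.max(v)
        order = np.argsort(c)
        k_m0 = float(np.interp(half, v[order], c[order]))
        if not np.isfinite(k_m0) or k_m0 <= 0:
            k_m0 = float(np.median(c))

    def mm(cc, vm, km):
        return vm * cc / (km + cc)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(
            mm, c, v, p0=(v_max0, max(k_m0, 1e-9)),
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20000,
        )
    se = np.sqrt(np.abs(np.diag(pcov)))
    at_boundary = popt[1] < 1e-6 * max(np.max(c), 1.0)
    return MichaelisMentenFit(v_max=popt[0], k_m=popt[1],
                              se_v_max=se[0], se_k_m=se[1],
                              at_boundary=bool(at_boundary))


def electron_flow(rate, gas: str):
    """Convert a gas rate to its electron-equivalent rate (x4 O2, x2 N2O)."""
    if gas not in ELECTRONS_PER_MOL:
        raise ValueError(f"unknown electron acceptor {gas!r}")
    return np.asarray(rate, dtype=float) * ELECTRONS_PER_MOL[gas]


@dataclass
class YieldFit:
    y_cells_per_mol: float
    se: float
    y_e_gcdw_per_mol_e: float | None  # g cell dry weight per mol electrons


def growth_yield(cell_counts, gas_consumed_mol, gas: str,
                 cell_dry_weight_fg: float | None = None) -> YieldFit:
    """Growth yield: slope of cells vs mol gas consumed.

    With a cell dry weight (fg/cell) the electron-based yield
    (g CDW per mol e-) is derived using 4 e-/O2 or 2 e-/N2O.
    """
    n = np.asarray(cell_counts, dtype=float)
    g = np.asarray(gas_consumed_mol, dtype=float)
    if n.size < 2 or g.size != n.size:
        raise ValueError("need >= 2 matched (consumption, cell-count) pairs")
    if np.ptp(g) == 0:
        raise ValueError("degenerate design: all consumptions equal")
    res = stats.linregress(g, n)
    y = res.slope
    y_e = None
    if cell_dry_weight_fg is not None:
        e_per_mol = ELECTRONS_PER_MOL[gas]
        y_e = y * cell_dry_weight_fg * 1e-15 / e_per_mol
    se = res.stderr if np.isfinite(res.stderr) else 0.0
    return YieldFit(y_cells_per_mol=y, se=se, y_e_gcdw_per_mol_e=y_e)


@dataclass
class OnsetResult:
    onset_um: float | None          # dissolved O2 at N2O-respiration onset
    onset_time_h: float | None

    @property
    def found(self) -> bool:
        return self.onset_um is not None


def o2_onset_threshold(o2_dissolved: DissolvedSeries, n2o_rates: RateSeries,
                       noise_floor_mol_h: float = 0.0) -> OnsetResult:
    """Dissolved O2 concentration at which net N2O consumption begins.

    Finds the first interval whose N2O consumption exceeds the noise floor
    and reports the concurrent dissolved O2 (interpolated). If N2O is never
    consumed, returns a no-onset result instead of raising.
    """
    cons = -n2o_rates.rate_mol_h
    idx = np.nonzero(cons > noise_floor_mol_h)[0]
    if idx.size == 0:
        return OnsetResult(onset_um=None, onset_time_h=None)
    t_on = n2o_rates.interval_midpoints_h[idx[0]]
    o2 = float(np.interp(t_on, o2_dissolved.times_h, o2_dissolved.concentration_um))
    return OnsetResult(onset_um=o2, onset_time_h=float(t_on))
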