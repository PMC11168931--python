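"""Synthetic-data generators for every stage of the pipeline.

Each generator is a pure function of its seed, produces data with the
statistical structure the corresponding analysis assumes, and returns the
generating ground truth alongside the data so recovery can be audited.

* :func:`gen_incubation` -- vial headspace curves from the bet-hedging
  simulator, sampled on a GC-like schedule with sampling-loss events and
  multiplicative measurement noise;
* :func:`gen_field` -- chamber-enclosure concentration ramps for a
  two-arm field campaign with diurnal (temperature-driven) flux cycles,
  transient event peaks (rain / re-fertilization analogues), a true
  treatment ratio and chamber-level lognormal noise;
* :func:`gen_campaign_emissions` -- the reduced statistical form of the
  same model (cumulated emissions per chamber) for coverage studies;
* :func:`gen_qpcr` -- standard curves (decade design) and optional
  inhibition series with additive Gaussian Cq noise;
* :func:`gen_survival` -- piecewise first-order decay series with
  multiplicative lognormal noise;
* :func:`gen_inventory` -- schema-valid emission inventories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bethedge import BetHedgeParams, simulate
from .constants import G_N_PER_MOL_N2O, R_GAS
from .fieldflux import EnclosureSeries
from .incubation import GasSeries, VialSpec
from .qpcr import QpcrCalibration, cq_from_copies
from .upscale import CATEGORIES

__all__ = [
    "NoiseSpec", "FieldModel",
    "gen_incubation", "gen_field", "gen_campaign_emissions",
    "gen_qpcr", "gen_survival", "gen_inventory",
]


@dataclass
class NoiseSpec:
    """One noise channel: multiplicative lognormal or additive Gaussian."""

    family: str = "lognormal"        # "lognormal" | "gaussian" | "none"
    scale: float = 0.0               # CV for lognormal, sd for gaussian

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")
        if self.family not in ("lognormal", "gaussian", "none"):
            raise ValueError(f"unknown noise family {self.family!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.family == "none" or self.scale == 0:
            return np.asarray(values, dtype=float).copy()
        if self.family == "lognormal":
            sigma = np.sqrt(np.log1p(self.scale**2))
            eps = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma,
                                size=np.shape(values))
            return values * eps
        return values + rng.normal(0.0, self.scale, size=np.shape(values))


# ---------------------------------------------------------------------------
# incubation
# ---------------------------------------------------------------------------

def gen_incubation(params: BetHedgeParams | None = None,
                   vial: VialSpec | None = None,
                   initial_headspace_mol: dict | None = None,
                   noise: NoiseSpec | None = None,
                   seed: int = 0,
                   t_end_h: float = 60.0,
                   sampling_interval_h: float = 1.0):
    """Simulated vial gas curves sampled on a GC-like schedule.

    Returns ``(series, truth)`` where ``series`` maps gas -> GasSeries with
    the sampling events registered, and ``truth`` records the generating
    parameters and the noiseless simulation.
    """
    params = params or BetHedgeParams()
    vial = vial or VialSpec()
    if initial_headspace_mol is None:
        initial_headspace_mol = {"O2": 9e-5, "N2O": 1e-4, "N2": 0.0}
    noise = noise or NoiseSpec(family="lognormal", scale=0.0)
    rng = np.random.default_rng(seed)

    schedule = np.arange(sampling_interval_h, t_end_h, sampling_interval_h)
    t_obs = np.concatenate([[0.0], schedule])
    sim = simulate(params, vial, initial_headspace_mol,
                   sampling_times_h=schedule, t_end_h=t_end_h, t_eval=t_obs)

    series = {}
    for gas, clean in (("O2", sim.o2_headspace_mol),
                       ("N2O", sim.n2o_headspace_mol),
                       ("N2", sim.n2_headspace_mol)):
        obs = np.interp(t_obs, sim.times_h, clean)
        noisy = np.clip(noise.apply(obs, rng), 0.0, None)
        series[gas] = GasSeries(gas=gas, times_h=t_obs, amount_mol=noisy,
                                sampling_events_h=schedule)
    truth = {
        "params": dict(params.__dict__),
        "initial_headspace_mol": dict(initial_headspace_mol),
        "noise": {"family": noise.family, "scale": noise.scale},
        "seed": seed,
        "simulation": sim,
    }
    return series, truth


# ---------------------------------------------------------------------------
# field campaign
# ---------------------------------------------------------------------------

@dataclass
class FieldModel:
    """Statistical model of a two-arm dynamic-chamber campaign.

    Flux levels are in ug N2O-N m-2 h-1. The control-arm flux path is
    baseline + diurnal sine + exponential-decay event pulses; the treated
    arm is the same path multiplied by ``true_ratio``. Chambers carry
    independent lognormal multipliers (level CV ``chamber_cv``).
    """

    baseline: float = 200.0
    diurnal_amplitude: float = 100.0
    diurnal_phase_h: float = 14.0            # flux peaks mid-afternoon
    event_times_h: tuple = (48.0, 180.0)
    event_magnitudes: tuple = (3000.0, 1500.0)
    event_decay_h: float = 18.0
    true_ratio: float = 0.5
    chamber_cv: float = 0.3
    n_chambers: int = 6
    paired: bool = False
    duration_h: float = 240.0
    measurement_interval_h: float = 4.0
    chamber_height_m: float = 0.2
    pressure_pa: float = 101325.0
    temperature_k: float = 288.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.true_ratio <= 1.0:
            raise ValueError("true_ratio must be in (0, 1]")
        if self.chamber_cv < 0:
            raise ValueError("chamber_cv must be >= 0")

    def flux_path(self, t_h: np.ndarray) -> np.ndarray:
        """Control-arm flux (ug N m-2 h-1) at campaign times ``t_h``."""
        t_h = np.asarray(t_h, dtype=float)
        q = self.baseline + self.diurnal_amplitude * np.sin(
            2.0 * np.pi * (t_h - self.diurnal_phase_h + 6.0) / 24.0)
        for t0, mag in zip(self.event_times_h, self.event_magnitudes):
            pulse = mag * np.exp(-(t_h - t0) / self.event_decay_h)
            q = q + np.where(t_h >= t0, pulse, 0.0)
        return np.clip(q, 0.0, None)


def _ug_n_h_to_mol_s(q_ug_n_m2_h) -> np.ndarray:
    return np.asarray(q_ug_n_m2_h, dtype=float) * 1e-6 / G_N_PER_MOL_N2O / 3600.0


def gen_field(model: FieldModel, enclosure_s: float = 180.0,
              points_per_enclosure: int = 19, ambient_ppm: float = 0.33):
    """Enclosure ramps for a full campaign, plus the generating truth.

    Each true flux is converted to a linear ppm ramp by inverting the
    chamber-flux formula (a = q R T / (1e-6 h p)), so flux processing
    recovers the generating flux exactly in the noiseless case. Returns
    ``(enclosures, truth)``; truth carries per-chamber true flux paths and
    the true cumulated-emission ratio (equal to ``true_ratio``).
    """
    rng = np.random.default_rng(model.seed)
    t_meas = np.arange(0.0, model.duration_h + 1e-9, model.measurement_interval_h)
    base = model.flux_path(t_meas)                      # ug N m-2 h-1
    sigma = np.sqrt(np.log1p(model.chamber_cv**2))

    enclosures: list[EnclosureSeries] = []
    chamber_flux_truth = {}
    t_enc = np.linspace(0.0, enclosure_s, points_per_enclosure)
    for arm, arm_scale in (("control", 1.0), ("treated", model.true_ratio)):
        for j in range(model.n_chambers):
            mult = rng.lognormal(-sigma**2 / 2.0, sigma) if model.chamber_cv else 1.0
            path = base * arm_scale * mult
            cid = f"{arm}_{j:02d}"
            chamber_flux_truth[cid] = path
            a = _ug_n_h_to_mol_s(path) * R_GAS * model.temperature_k / (
                1e-6 * model.chamber_height_m * model.pressure_pa)  # ppm/s
            for k, t0 in enumerate(t_meas):
                conc = ambient_ppm + a[k] * t_enc
                enclosures.append(EnclosureSeries(
                    chamber_id=cid, treatment=arm, times_s=t_enc.copy(),
                    concentration_ppm=conc,
                    chamber_height_m=model.chamber_height_m,
                    pressure_pa=model.pressure_pa,
                    temperature_k=model.temperature_k,
                    start_time_h=float(t0)))
    truth = {
        "model": dict(model.__dict__),
        "measurement_times_h": t_meas,
        "control_path_ug_n_m2_h": base,
        "chamber_flux_paths": chamber_flux_truth,
        "true_cumulative_ratio": model.true_ratio,
    }
    return enclosures, truth


def gen_campaign_emissions(model: FieldModel, rng: np.random.Generator):
    """Cumulated emissions per chamber under the field model, directly.

    The trapezoid of the (noise-free) flux path times the chamber
    multiplier -- the statistical reduction of :func:`gen_field` used for
    interval-coverage studies. Returns ``(treated, control)`` arrays; for a
    paired model the chamber multipliers are shared within pairs so the
    per-pair ratio is ``true_ratio`` up to pair noise.
    """
    t = np.arange(0.0, model.duration_h + 1e-9, model.measurement_interval_h)
    base_cum = float(np.trapezoid(model.flux_path(t), t))
    sigma = np.sqrt(np.log1p(model.chamber_cv**2))
    n = model.n_chambers
    if model.paired:
        plot = rng.lognormal(-sigma**2 / 2.0, sigma, size=n)
        within = np.sqrt(np.log1p((model.chamber_cv / 2.0) ** 2))
        ex = rng.lognormal(-within**2 / 2.0, within, size=n)
        ey = rng.lognormal(-within**2 / 2.0, within, size=n)
        treated = base_cum * model.true_ratio * plot * ex
        control = base_cum * plot * ey
    else:
        treated = base_cum * model.true_ratio * rng.lognormal(
            -sigma**2 / 2.0, sigma, size=n)
        control = base_cum * rng.lognormal(-sigma**2 / 2.0, sigma, size=n)
    return treated, control


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def gen_qpcr(cal: QpcrCalibration | None = None,
             copies=None, cq_noise_sd: float = 0.0, seed: int = 0,
             inhibition_delta_cq: float = 0.0,
             inhibition_below_dilution: float = 10.0,
             dilution_factors=None):
    """Standard curves and an optional spiked dilution series.

    Defaults mirror the published calibration: (N_T, e) = (7.68e10, 0.85)
    and standards at 2.4e1 ... 2.4e6 templates per tube (decade design).
    Returns ``(standards_df, dilution_df, truth)``; ``dilution_df`` is None
    unless ``dilution_factors`` is given. ``inhibition_delta_cq`` adds a Cq
    offset at dilution factors below ``inhibition_below_dilution``.
    """
    cal = cal or QpcrCalibration(n_t=7.68e10, e=0.85)
    if copies is None:
        copies = 2.4 * 10.0 ** np.arange(1, 7)
    copies = np.asarray(copies, dtype=float)
    rng = np.random.default_rng(seed)
    cq = np.array([cq_from_copies(c, cal) for c in copies])
    cq = cq + rng.normal(0.0, cq_noise_sd, size=cq.size) if cq_noise_sd else cq
    standards = pd.DataFrame({"known_copies": copies, "cq": cq})

    dilution_df = None
    spike = None
    if dilution_factors is not None:
        d = np.asarray(dilution_factors, dtype=float)
        spike = float(copies.max())
        m = np.array([cq_from_copies(spike / dd, cal) for dd in d])
        m = m + np.where(d < inhibition_below_dilution, inhibition_delta_cq, 0.0)
        if cq_noise_sd:
            m = m + rng.normal(0.0, cq_noise_sd, size=m.size)
        dilution_df = pd.DataFrame({"dilution_factor": d, "cq": m})
    truth = {"n_t": cal.n_t, "e": cal.e, "cq_noise_sd": cq_noise_sd,
             "seed": seed, "spike_copies_undiluted": spike,
             "inhibition_delta_cq": inhibition_delta_cq,
             "inhibition_below_dilution": inhibition_below_dilution}
    return standards, dilution_df, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def gen_survival(n_0: float, phases, noise_cv: float = 0.0, seed: int = 0,
                 samples_per_day: float = 1.0):
    """Piecewise first-order decay series with lognormal noise.

    ``phases`` is a list of (duration_days, d_per_day); abundances are
    generated at ``samples_per_day`` resolution and stay positive for any
    seed (lognormal support). Returns ``(days, abundances, truth)``.
    """
    if not phases:
        raise ValueError("phase list must be non-empty")
    rng = np.random.default_rng(seed)
    total = sum(p[0] for p in phases)
    days = np.arange(0.0, total + 1e-9, 1.0 / samples_per_day)
    clean = np.empty_like(days)
    t0, n_start = 0.0, float(n_0)
    for dur, d in phases:
        mask = (days >= t0 - 1e-12) & (days <= t0 + dur + 1e-12)
        clean[mask] = n_start * np.exp(-d * (days[mask] - t0))
        n_start = n_start * np.exp(-d * dur)
        t0 += dur
    if noise_cv:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        clean = clean * rng.lognormal(-sigma**2 / 2.0, sigma, size=clean.size)
    truth = {"n_0": n_0, "phases": list(phases), "noise_cv": noise_cv,
             "seed": seed}
    return days, clean, truth


# ---------------------------------------------------------------------------
# inventory
# ---------------------------------------------------------------------------

def gen_inventory(n_regions: int = 1, seed: int = 0) -> pd.DataFrame:
    """Schema-valid long-form emission inventory.

    ``n_regions = 1`` returns a deterministic toy region (total 100 kt,
    liquid manure 10 kt) used in the worked examples; larger inventories are
    random but always satisfy category sums <= agricultural <= total.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rows = []
    if n_regions >= 1:
        toy = {"liquid_manure_applied": 10.0, "solid_manure_applied": 8.0,
               "mineral_fertilizer": 15.0, "plant_residues": 5.0, "other": 12.0}
        for cat, kt in toy.items():
            rows.append({"region": "toyland", "total_kt": 100.0,
                         "agric_kt": 50.0, "category": cat, "emission_kt": kt})
    rng = np.random.default_rng(seed)
    for i in range(1, n_regions):
        total = float(rng.uniform(20.0, 500.0))
        agric = total * float(rng.uniform(0.3, 0.7))
        shares = rng.dirichlet(np.ones(len(CATEGORIES))) * agric * \
            float(rng.uniform(0.6, 0.95))
        for cat, kt in zip(CATEGORIES, shares):
            rows.append({"region": f"region_{i:03d}", "total_kt": total,
                         "agric_kt": agric, "category": cat,
                         "emission_kt": float(kt)})
    return pd.DataFrame(rows, columns=["region", "total_kt", "agric_kt",
                                       "category", "emission_kt"])
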