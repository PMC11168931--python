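"""Two-subpopulation (bet-hedging) batch-vial respiration simulator.

Model
-----
A stirred batch vial contains two deterministic subpopulations of an
N2O-respiring strain: a fraction ``f_nosz`` that expresses the N2O
reductase NosZ in response to O2 depletion, and the complement that does
not. Both subpopulations grow aerobically with Michaelis-Menten kinetics in
the dissolved O2 concentration. Once dissolved O2 falls below ``o2_switch``
the NosZ-expressing subpopulation additionally grows by N2O respiration
(Michaelis-Menten in dissolved N2O), reducing N2O to N2 mole for mole; the
non-expressing subpopulation stops respiring when O2 is gone. Gas exchange
between headspace and liquid is first-order in the departure from Henry-law
equilibrium with volumetric transfer coefficient kLa. Headspace sampling
events instantaneously dilute every headspace gas by the sampled fraction
(replaced by inert gas), which produces the apparent slow decline of
headspace N2O before its biological consumption starts.

State is integrated in mol (gases), mol/l (liquid) and cells, with time in
hours, by a stiff-capable solver with exact event handling at sampling
times and at the O2 switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .constants import ATM_PA, R_GAS, T0_K, henry_coefficient
from .incubation import GasSeries, VialSpec

__all__ = ["BetHedgeParams", "SimResult", "simulate", "fit_fnosz",
           "electron_flow_curve", "FnoszFit"]

RTOL = 1e-9
ATOL_MOL = 1e-12


@dataclass
class BetHedgeParams:
    """Kinetic parameters of the bet-hedging respiration model.

    Defaults are the fitted respiratory parameters of the Cloacibacterium
    inoculant strain: mu_max 0.29 / 0.11 h-1 and K_m 0.9 / 12.9 uM for O2 /
    N2O, yields mu_max/V_max, O2 switch at 2 uM dissolved O2, and a NosZ-
    expressing fraction of 0.03.
    """

    f_nosz: float = 0.03
    mu_max_o2: float = 0.29          # h-1
    mu_max_n2o: float = 0.11         # h-1
    k_m_o2: float = 0.9              # uM
    k_m_n2o: float = 12.9            # uM
    y_o2: float = 0.29 / 0.72e-15    # cells per mol O2  (= mu_max / V_max)
    y_n2o: float = 0.11 / 0.66e-15   # cells per mol N2O
    n_ini: float = 2e8               # cells per vial
    o2_switch: float = 2.0           # uM dissolved O2

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_nosz <= 1.0:
            raise ValueError("f_nosz must be in [0, 1]")
        for name in ("mu_max_o2", "mu_max_n2o", "k_m_o2", "k_m_n2o",
                     "y_o2", "y_n2o", "n_ini"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimResult:
    """Trajectories of one simulated vial (times in h, amounts in mol)."""

    times_h: np.ndarray
    o2_headspace_mol: np.ndarray
    n2o_headspace_mol: np.ndarray
    n2_headspace_mol: np.ndarray
    o2_aq_um: np.ndarray
    n2o_aq_um: np.ndarray
    cells_nosz: np.ndarray
    cells_other: np.ndarray
    o2_consumption_mol_h: np.ndarray
    n2o_consumption_mol_h: np.ndarray
    cum_o2_mol: np.ndarray          # cumulated biological O2 consumption
    cum_n2o_mol: np.ndarray
    removed_by_sampling_mol: dict = field(default_factory=dict)  # per gas
    params: BetHedgeParams | None = None
    vial: VialSpec | None = None

    @property
    def cells_total(self) -> np.ndarray:
        return self.cells_nosz + self.cells_other

    @property
    def electron_flow_mol_h(self) -> np.ndarray:
        return 4.0 * self.o2_consumption_mol_h + 2.0 * self.n2o_consumption_mol_h

    def headspace_series(self, gas: str, sampling_times_h=None) -> GasSeries:
        """Package a headspace trajectory as a GasSeries for reprocessing."""
        amounts = {"O2": self.o2_headspace_mol, "N2O": self.n2o_headspace_mol,
                   "N2": self.n2_headspace_mol}[gas]
        ev = np.asarray(sampling_times_h if sampling_times_h is not None else [])
        return GasSeries(gas=gas, times_h=self.times_h, amount_mol=amounts,
                         sampling_events_h=ev)


# state layout: [O2_h, N2O_h, N2_h, O2_aq(mol), N2O_aq(mol), N+, N-, cumO2, cumN2O]
_IDX = dict(o2h=0, n2oh=1, n2h=2, o2aq=3, n2oaq=4, np=5, nm=6, cumo2=7, cumn2o=8)


def _rates(y, p: BetHedgeParams, vial: VialSpec, k0_o2: float, k0_n2o: float,
           nosz_active: bool):
    """Time derivatives + the two biological consumption rates (mol/h)."""
    v_liq = vial.liquid_volume_ml * 1e-3            # l
    v_head = vial.headspace_volume_ml * 1e-6        # m3
    t_k = vial.temperature_c + T0_K

    c_o2 = max(y[3], 0.0) / v_liq                   # mol/l
    c_n2o = max(y[4], 0.0) / v_liq
    n_plus, n_minus = max(y[5], 0.0), max(y[6], 0.0)

    # Henry-law equilibrium concentrations from headspace partial pressures
    p_o2_atm = max(y[0], 0.0) * R_GAS * t_k / v_head / ATM_PA
    p_n2o_atm = max(y[1], 0.0) * R_GAS * t_k / v_head / ATM_PA
    c_eq_o2 = k0_o2 * p_o2_atm
    c_eq_n2o = k0_n2o * p_n2o_atm

    transfer_o2 = vial.kla_for("O2") * (c_eq_o2 - c_o2) * v_liq      # mol/h
    transfer_n2o = vial.kla_for("N2O") * (c_eq_n2o - c_n2o) * v_liq

    km_o2 = p.k_m_o2 * 1e-6                         # uM -> mol/l
    km_n2o = p.k_m_n2o * 1e-6
    mu_o2 = p.mu_max_o2 * c_o2 / (km_o2 + c_o2)
    r_o2 = mu_o2 * (n_plus + n_minus) / p.y_o2      # mol O2 / h

    if nosz_active:
        mu_n2o = p.mu_max_n2o * c_n2o / (km_n2o + c_n2o)
        r_n2o = mu_n2o * n_plus / p.y_n2o
    else:
        mu_n2o = 0.0
        r_n2o = 0.0

    dy = np.empty(9)
    dy[0] = -transfer_o2
    dy[1] = -transfer_n2o
    dy[2] = r_n2o                    # N2 released to headspace, mol per mol N2O
    dy[3] = transfer_o2 - r_o2
    dy[4] = transfer_n2o - r_n2o
    dy[5] = (mu_o2 + mu_n2o) * n_plus
    dy[6] = mu_o2 * n_minus
    dy[7] = r_o2
    dy[8] = r_n2o
    return dy, r_o2, r_n2o


def simulate(params: BetHedgeParams, vial: VialSpec,
             initial_headspace_mol: dict,
             sampling_times_h=(), t_end_h: float = 60.0,
             t_eval: np.ndarray | None = None,
             n_output: int = 400) -> SimResult:
    """Integrate one vial through O2 depletion and N2O respiration.

    ``initial_headspace_mol`` maps gas name -> mol per vial for O2, N2O and
    (optionally) N2; the liquid starts at Henry-law equilibrium with the
    headspace. Sampling events (headspace dilution by the vial's sampling
    fraction) occur at ``sampling_times_h``.
    """
    sampling = np.sort(np.asarray(sampling_times_h, dtype=float))
    if sampling.size and (sampling[0] < 0 or sampling[-1] > t_end_h):
        raise ValueError("sampling schedule must lie within [0, t_end]")
    if any(v < 0 for v in initial_headspace_mol.values()):
        raise ValueError("initial amounts must be >= 0")

    k0_o2 = henry_coefficient("O2", vial.temperature_c)
    k0_n2o = henry_coefficient("N2O", vial.temperature_c)
    v_liq = vial.liquid_volume_ml * 1e-3
    v_head = vial.headspace_volume_ml * 1e-6
    t_k = vial.temperature_c + T0_K

    o2_0 = initial_headspace_mol.get("O2", 0.0)
    n2o_0 = initial_headspace_mol.get("N2O", 0.0)
    n2_0 = initial_headspace_mol.get("N2", 0.0)
    c_eq = lambda n, k0: k0 * (n * R_GAS * t_k / v_head / ATM_PA)
    y = np.array([
        o2_0, n2o_0, n2_0,
        c_eq(o2_0, k0_o2) * v_liq, c_eq(n2o_0, k0_n2o) * v_liq,
        params.f_nosz * params.n_ini, (1.0 - params.f_nosz) * params.n_ini,
        0.0, 0.0,
    ])

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end_h, n_output)
    t_eval = np.asarray(t_eval, dtype=float)

    switch_c = params.o2_switch * 1e-6              # mol/l
    nosz_active = y[3] / v_liq < switch_c

    atol = np.array([ATOL_MOL] * 5 + [1.0, 1.0] + [ATOL_MOL] * 2)
    f = vial.sampling_fraction
    removed = {"O2": 0.0, "N2O": 0.0, "N2": 0.0}

    seg_bounds = np.concatenate([[0.0], sampling[(sampling > 0) & (sampling < t_end_h)],
                                 [t_end_h]])
    out_t, out_y, out_r = [], [], []

    def switch_event(t, yy):
        return yy[3] / v_liq - switch_c
    switch_event.terminal = True
    switch_event.direction = -1.0

    t_now = seg_bounds[0]
    for t_next in seg_bounds[1:]:
        while t_now < t_next - 1e-12:
            rhs = lambda t, yy: _rates(yy, params, vial, k0_o2, k0_n2o, nosz_active)[0]
            events = None if nosz_active else [switch_event]
            te = t_eval[(t_eval >= t_now) & (t_eval <= t_next)]
            sol = solve_ivp(rhs, (t_now, t_next), y, method="LSODA",
                            t_eval=te if te.size else None, dense_output=True,
                            events=events, rtol=RTOL, atol=atol, max_step=np.inf)
            if not sol.success:
                raise RuntimeError(
                    f"ODE solver failed at t={t_now:.3f} h with state {y!r}: "
                    f"{sol.message}")
            for k in range(sol.t.size):
                if out_t and sol.t[k] <= out_t[-1] + 1e-12:
                    continue
                out_t.append(sol.t[k])
                out_y.append(sol.y[:, k])
                _, ro, rn = _rates(sol.y[:, k], params, vial, k0_o2, k0_n2o,
                                   nosz_active)
                out_r.append((ro, rn))
            if sol.status == 1:        # O2 crossed the switch threshold
                t_now = float(sol.t_events[0][0])
                y = sol.y_events[0][0].copy()
                # bracket the rate discontinuity so quadrature on the output
                # grid sees the jump in N2O consumption at the switch
                if not out_t or t_now > out_t[-1] + 1e-12:
                    _, ro, rn = _rates(y, params, vial, k0_o2, k0_n2o, False)
                    out_t.append(t_now)
                    out_y.append(y.copy())
                    out_r.append((ro, rn))
                nosz_active = True
                _, ro, rn = _rates(y, params, vial, k0_o2, k0_n2o, True)
                out_t.append(out_t[-1] + 1e-9)
                out_y.append(y.copy())
                out_r.append((ro, rn))
            else:
                t_now = t_next
                y = sol.sol(t_next).copy()
        # sampling event at the segment boundary
        if np.any(np.isclose(sampling, t_next)):
            for gas, i in (("O2", 0), ("N2O", 1), ("N2", 2)):
                removed[gas] += y[i] * f
                y[i] *= (1.0 - f)

    times = np.asarray(out_t)
    ys = np.asarray(out_y).T
    ys[:5] = np.clip(ys[:5], 0.0, None)   # solver-tolerance negatives
    ro = np.array([r[0] for r in out_r])
    rn = np.array([r[1] for r in out_r])
    return SimResult(
        times_h=times,
        o2_headspace_mol=ys[0], n2o_headspace_mol=ys[1], n2_headspace_mol=ys[2],
        o2_aq_um=ys[3] / v_liq * 1e6, n2o_aq_um=ys[4] / v_liq * 1e6,
        cells_nosz=ys[5], cells_other=ys[6],
        o2_consumption_mol_h=ro, n2o_consumption_mol_h=rn,
        cum_o2_mol=ys[7], cum_n2o_mol=ys[8],
        removed_by_sampling_mol=removed, params=params, vial=vial,
    )


def electron_flow_curve(sim: SimResult) -> np.ndarray:
    """Total electron flow, mol e- per vial per hour: 4*r_O2 + 2*r_N2O."""
    return sim.electron_flow_mol_h


# ---------------------------------------------------------------------------
# F_NosZ estimation
# ---------------------------------------------------------------------------

@dataclass
class FnoszFit:
    f_nosz: float
    loss: float
    grid: list                      # (f, loss) samples of the loss surface
    unidentifiable: bool = False
    n_ini: float | None = None


def _sim_loss(f: float, observed: dict, params: BetHedgeParams, vial: VialSpec,
              initial_headspace_mol: dict, sampling_times_h, n_ini=None) -> float:
    kw = {"f_nosz": float(np.clip(f, 0.0, 1.0))}
    if n_ini is not None:
        kw["n_ini"] = float(n_ini)
    p = BetHedgeParams(**{**params.__dict__, **kw})
    ref = observed[next(iter(observed))]
    t_end = float(ref.times_h[-1])
    sim = simulate(p, vial, initial_headspace_mol,
                   sampling_times_h=sampling_times_h, t_end_h=t_end,
                   t_eval=ref.times_h)
    loss = 0.0
    for gas, obs in observed.items():
        model = {"O2": sim.o2_headspace_mol, "N2O": sim.n2o_headspace_mol,
                 "N2": sim.n2_headspace_mol}[gas]
        model = np.interp(obs.times_h, sim.times_h, model)
        scale = np.ptp(obs.amount_mol)
        if scale == 0:
            scale = max(np.max(obs.amount_mol), 1.0)
        loss += float(np.sum(((model - obs.amount_mol) / scale) ** 2))
    return loss


def fit_fnosz(observed: dict, params: BetHedgeParams, vial: VialSpec,
              initial_headspace_mol: dict, sampling_times_h=(),
              bounds: tuple = (1e-4, 1.0),
              grid=(0.01, 0.05, 0.2, 0.8),
              fit_n_ini: bool = False) -> FnoszFit:
    """Estimate the NosZ-expressing fraction from observed headspace curves.

    ``observed`` maps gas name ("O2", "N2O") to a GasSeries. The loss is the
    sum over gases of squared residuals normalized by each gas's data range.
    A fixed multistart grid seeds a bounded scalar refinement around the
    best grid point; if the loss surface is flat across the grid (no O2 ->
    N2O transition in the data) the result is flagged unidentifiable.
    """
    args = (observed, params, vial, initial_headspace_mol, sampling_times_h)
    grid_pts = [(g, _sim_loss(g, *args)) for g in grid]
    losses = np.array([l for _, l in grid_pts])
    # flat surface: every grid point fits to solver-noise level, or the
    # spread across the grid is negligible -- no transition in the data
    if losses.max() < 1e-10 or np.ptp(losses) < 1e-3 * losses.max():
        return FnoszFit(f_nosz=float("nan"), loss=float(losses.min()),
                        grid=grid_pts, unidentifiable=True)
    f_best = grid_pts[int(np.argmin(losses))][0]
    lo = max(bounds[0], f_best / 5.0)
    hi = min(bounds[1], f_best * 5.0)
    res = minimize_scalar(lambda f: _sim_loss(f, *args), bounds=(lo, hi),
                          method="bounded", options={"xatol": 1e-5})
    f_hat, loss = float(res.x), float(res.fun)
    n_ini_hat = None
    if fit_n_ini:
        from scipy.optimize import least_squares

        def resid(x):
            return np.sqrt(_sim_loss(x[0], observed, params, vial,
                                     initial_headspace_mol, sampling_times_h,
                                     n_ini=np.exp(x[1])))
        ls = least_squares(resid, x0=[f_hat, np.log(params.n_ini)],
                           bounds=([bounds[0], np.log(params.n_ini) - 5],
                                   [bounds[1], np.log(params.n_ini) + 5]),
                           xtol=1e-10, ftol=1e-10)
        f_hat, n_ini_hat = float(ls.x[0]), float(np.exp(ls.x[1]))
        loss = float(ls.fun[0] ** 2)
    return FnoszFit(f_nosz=f_hat, loss=loss, grid=grid_pts, n_ini=n_ini_hat)
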