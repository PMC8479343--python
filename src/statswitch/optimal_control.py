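"""Optimal infusion scheduling by Pontryagin's principle and the
forward-backward sweep.

The running cost penalizes tumour deviation from a desired volume, the
anti-apoptotic Bcl-2 level and the (negated) pro-apoptotic BAX level, plus
linear and quadratic infusion costs:

    integral of  A1 (T - T_bar)^2 + A2 B^2 - A3 X^2
                 + C1 u_S + C2 u_D + C3 u_S^2 + C4 u_D^2  dt.

Each sweep iteration solves the state system forward, the costate system
backward from lambda(t_e) = 0, and updates the controls from Hamiltonian
stationarity, u* = clip((-C_lin - lambda_drug) / (2 C_quad), 0, u_max).
Two update schemes are provided: the classic relaxed fixed-point update
and a projected-gradient step with backtracking line search (the default,
which descends the objective monotonically and stops at a stationarity
point).  The binary apoptosis switch is handled either by freezing it
along the forward pass ('frozen') or by a logistic smoothing that is
differentiated through in the adjoint ('smooth', the default for the
sweep, steepness 100).

Strategy I optimizes both infusions freely over the horizon; Strategy II
optimizes the IFN-beta profile only inside the 'S' slots of a given
S/D scheme, with the DDP pulses of that scheme held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .dosing import PulseControl, PulseSchedule, build_pulse_controls
from .model import default_initial_state, _sample_half_grid
from .params import ModelParams, SystemState, Thresholds

__all__ = [
    "ControlWeights",
    "ControlProblem",
    "ControlSolution",
    "STRATEGY_I_WEIGHTS",
    "STRATEGY_II_WEIGHTS",
    "objective",
    "objective_arrays",
    "adjoint_rhs",
    "control_update",
    "forward_backward_sweep",
    "run_strategy_I",
    "run_strategy_II",
    "half_life_experiment",
]


@dataclass(frozen=True)
class ControlWeights:
    """Objective weights; quadratic weights of actively optimized controls
    must be positive for the interior stationarity formula."""

    A1: float
    A2: float
    A3: float
    C1: float
    C2: float
    C3: float
    C4: float
    T_bar: float
    t_s: float = 0.0
    t_e: float = 30.0

    def __post_init__(self) -> None:
        for name in ("A1", "A2", "A3", "C1", "C2", "C3", "C4"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be non-negative")
        if not self.t_e > self.t_s:
            raise ValueError("horizon must have positive length")


STRATEGY_I_WEIGHTS = ControlWeights(1.0, 0.0, 0.0, 4e-5, 1e-5, 4e-5, 1e-5, 0.0)
STRATEGY_II_WEIGHTS = ControlWeights(12.0, 1.0, 4.0, 2e-2, 0.0, 2e-2, 0.0, 1.7634)


@dataclass
class ControlProblem:
    """A discretized optimal-control problem on a uniform grid."""

    params: ModelParams
    thresholds: Thresholds
    ic: SystemState
    weights: ControlWeights
    u_S_max: float = 50.0
    u_D_max: float = 100.0
    n_steps: int = 3000
    optimize_S: bool = True
    optimize_D: bool = False
    mask_S: np.ndarray | None = None  # bool per grid node; None = everywhere
    mask_D: np.ndarray | None = None
    fixed_u_S: Callable[[float], float] | None = None  # background when not optimized
    fixed_u_D: Callable[[float], float] | None = None
    indicator_mode: str = "smooth"  # 'smooth' | 'frozen'
    smooth_k: float = 100.0

    def __post_init__(self) -> None:
        if self.u_S_max < 0 or self.u_D_max < 0:
            raise ValueError("control bounds must be non-negative")
        if self.optimize_S and self.weights.C3 <= 0:
            raise ValueError(
                "optimizing u_S requires a positive quadratic weight C3 "
                "(bang-bang controls are out of scope)"
            )
        if self.optimize_D and self.weights.C4 <= 0:
            raise ValueError(
                "optimizing u_D requires a positive quadratic weight C4 "
                "(bang-bang controls are out of scope)"
            )
        if self.indicator_mode not in ("smooth", "frozen"):
            raise ValueError("indicator_mode must be 'smooth' or 'frozen'")

    # -- grid helpers -----------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return np.linspace(self.weights.t_s, self.weights.t_e, self.n_steps + 1)

    @property
    def dt(self) -> float:
        return (self.weights.t_e - self.weights.t_s) / self.n_steps

    def node_mask(self, which: str) -> np.ndarray:
        m = self.mask_S if which == "S" else self.mask_D
        if m is None:
            return np.ones(self.n_steps + 1, bool)
        m = np.asarray(m, bool)
        if m.shape != (self.n_steps + 1,):
            raise ValueError("mask length must match the grid")
        return m

    def background(self, which: str) -> np.ndarray:
        u = self.fixed_u_S if which == "S" else self.fixed_u_D
        if u is None:
            return np.zeros(2 * self.n_steps + 1)
        return _sample_half_grid(u, self.t)


@dataclass
class ControlSolution:
    t: np.ndarray
    u_S: np.ndarray
    u_D: np.ndarray
    states: np.ndarray
    adjoint: np.ndarray
    objective: float
    converged: bool
    iterations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def total_S(self) -> float:
        return float(np.trapezoid(self.u_S, self.t))

    @property
    def total_D(self) -> float:
        return float(np.trapezoid(self.u_D, self.t))

    def to_frame(self) -> pd.DataFrame:
        from .params import STATE_VARS

        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t", self.t)
        df["uS"] = self.u_S
        df["uD"] = self.u_D
        for i in range(8):
            df[f"lambda_{i + 1}"] = self.adjoint[:, i]
        return df


# -- objective and adjoint -------------------------------------------------

def objective_arrays(t, states, u_S, u_D, weights: ControlWeights) -> float:
    """Composite-trapezoid value of the running cost on the given grid."""
    t = np.asarray(t, float)
    if t[0] > weights.t_s + 1e-9 or t[-1] < weights.t_e - 1e-9:
        raise ValueError("grid does not cover the horizon")
    B = states[:, 2]
    X = states[:, 3]
    T = states[:, 4]
    w = weights
    integrand = (
        w.A1 * (T - w.T_bar) ** 2
        + w.A2 * B**2
        - w.A3 * X**2
        + w.C1 * np.asarray(u_S)
        + w.C2 * np.asarray(u_D)
        + w.C3 * np.asarray(u_S) ** 2
        + w.C4 * np.asarray(u_D) ** 2
    )
    return float(np.trapezoid(integrand, t))


def objective(trajectory, u_S, u_D, weights: ControlWeights) -> float:
    """Objective of a Trajectory with control values sampled on its grid."""
    t = trajectory.t
    uS = np.array([float(u_S(x)) for x in t]) if callable(u_S) else np.asarray(u_S)
    uD = np.array([float(u_D(x)) for x in t]) if callable(u_D) else np.asarray(u_D)
    return objective_arrays(t, trajectory.states, uS, uD, weights)


def adjoint_rhs(state, adjoint, t, problem: ControlProblem) -> np.ndarray:
    """Costate derivative -dH/dx at one time point (indicator per the
    problem's mode; 'frozen' freezes it at the value implied by the state)."""
    y = np.asarray(state, float)
    lam = np.asarray(adjoint, float)
    p = _kernels.pack_params(problem.params, problem.thresholds)
    mode = _kernels.SMOOTH if problem.indicator_mode == "smooth" else _kernels.SHARP
    w = problem.weights
    out = _kernels.adjoint_rhs_packed(lam, y, p, mode, problem.smooth_k, w.A1, w.A2, w.A3, w.T_bar)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite adjoint derivative")
    return out


def control_update(
    lambda_S: np.ndarray,
    lambda_D: np.ndarray,
    weights: ControlWeights,
    bounds: tuple[float, float],
    masks: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Hamiltonian stationarity update, clipped to the bounds and
    zeroed off the support masks."""
    u_S_max, u_D_max = bounds
    m_S, m_D = masks
    w = weights
    u_S = np.zeros_like(lambda_S)
    u_D = np.zeros_like(lambda_D)
    if w.C3 > 0:
        u_S = np.clip((-w.C1 - lambda_S) / (2 * w.C3), 0.0, u_S_max) * m_S
    if w.C4 > 0:
        u_D = np.clip((-w.C2 - lambda_D) / (2 * w.C4), 0.0, u_D_max) * m_D
    return u_S, u_D


# -- the sweep -------------------------------------------------------------

def _nodes_to_half(u: np.ndarray) -> np.ndarray:
    """Node values -> half-step grid (midpoints by averaging)."""
    n = len(u) - 1
    h = np.empty(2 * n + 1)
    h[0::2] = u
    h[1::2] = 0.5 * (u[:-1] + u[1:])
    return h


def forward_backward_sweep(
    problem: ControlProblem,
    u_S0: np.ndarray | None = None,
    u_D0: np.ndarray | None = None,
    *,
    relaxation: float = 0.5,
    tol: float = 1e-3,
    max_iter: int = 4000,
    update_scheme: str = "gradient",
    grad_step0: float = 1e-3,
    gtol: float = 1e-2,
) -> ControlSolution:
    """Solve the problem by forward-backward sweeping.

    update_scheme='gradient' (default): projected-gradient step on the
    reduced objective with backtracking line search; monotone in the
    objective, stopping when the projected stationarity residual
    (|dH/du| on interior arcs, one-sided at the bounds) falls below
    ``gtol`` or no descent step exists.
    update_scheme='relaxed': classic u <- c u_cand + (1 - c) u with the
    relaxation halved whenever the objective would increase; stops when
    the relative L1 control change drops below ``tol``.
    """
    if not 0 < relaxation <= 1:
        raise ValueError("relaxation must be in (0, 1]")
    if update_scheme not in ("gradient", "relaxed"):
        raise ValueError("unknown update scheme")
    pr = problem
    w = pr.weights
    t = pr.t
    dt = pr.dt
    N = pr.n_steps
    p = _kernels.pack_params(pr.params, pr.thresholds)
    mode = _kernels.SMOOTH if pr.indicator_mode == "smooth" else _kernels.SHARP
    ks = pr.smooth_k
    y0 = pr.ic.as_array()
    m_S = pr.node_mask("S") & np.full(N + 1, pr.optimize_S)
    m_D = pr.node_mask("D") & np.full(N + 1, pr.optimize_D)
    bg_S = pr.background("S")
    bg_D = pr.background("D")

    def run_forward(uS_nodes, uD_nodes):
        uS_half = bg_S + _nodes_to_half(uS_nodes * m_S)
        uD_half = bg_D + _nodes_to_half(uD_nodes * m_D)
        Y = _kernels.rk4_forward(y0, uS_half, uD_half, dt, p, mode, ks)
        JV = objective_arrays(t, Y, uS_half[0::2], uD_half[0::2], w)
        return Y, JV

    uS = np.zeros(N + 1) if u_S0 is None else np.asarray(u_S0, float).copy()
    uD = np.zeros(N + 1) if u_D0 is None else np.asarray(u_D0, float).copy()
    uS *= m_S
    uD *= m_D
    Y, J = run_forward(uS, uD)
    def proj_residual(g, u, m, umax):
        if not m.any():
            return 0.0
        r = np.where(u <= 1e-12, np.maximum(-g, 0.0),
                     np.where(u >= umax - 1e-12, np.maximum(g, 0.0), np.abs(g)))
        return float(np.max(r[m]))

    log = []
    converged = False
    residual = np.nan
    c = relaxation
    eta = grad_step0
    for it in range(max_iter):
        L = _kernels.rk4_backward(Y, dt, p, mode, ks, w.A1, w.A2, w.A3, w.T_bar)
        if update_scheme == "relaxed":
            cand_S, cand_D = control_update(
                L[:, 5], L[:, 7], w, (pr.u_S_max, pr.u_D_max), (m_S, m_D)
            )
            accepted = False
            cc = c
            for _ in range(30):
                nS = cc * cand_S + (1 - cc) * uS
                nD = cc * cand_D + (1 - cc) * uD
                Yn, Jn = run_forward(nS, nD)
                if Jn < J - 1e-12:
                    accepted = True
                    break
                cc *= 0.5
            step = cc
        else:
            gS = (w.C1 + 2 * w.C3 * uS + L[:, 5]) * m_S
            gD = (w.C2 + 2 * w.C4 * uD + L[:, 7]) * m_D
            residual = max(proj_residual(gS, uS, m_S, pr.u_S_max),
                           proj_residual(gD, uD, m_D, pr.u_D_max))
            if residual < gtol:
                converged = True
                log.append(dict(iteration=it, objective=J, rel_change=0.0,
                                step=eta, residual=residual))
                break
            accepted = False
            for _ in range(40):
                nS = np.clip(uS - eta * gS, 0.0, pr.u_S_max) * m_S
                nD = np.clip(uD - eta * gD, 0.0, pr.u_D_max) * m_D
                Yn, Jn = run_forward(nS, nD)
                if Jn < J - 1e-12:
                    accepted = True
                    break
                eta *= 0.5
            step = eta
            eta *= 2.0
        if not accepted:
            converged = True  # no descent available: (projected) stationarity
            log.append(dict(iteration=it, objective=J, rel_change=0.0,
                            step=step, residual=residual))
            break
        denom = max(np.sum(np.abs(nS)) + np.sum(np.abs(nD)), 1e-12)
        rel = (np.sum(np.abs(nS - uS)) + np.sum(np.abs(nD - uD))) / denom
        uS, uD, Y, J = nS, nD, Yn, Jn
        c = min(step * 2, relaxation)
        log.append(dict(iteration=it, objective=J, rel_change=rel,
                        step=step, residual=residual))
        if update_scheme == "relaxed" and rel < tol and it > 0:
            converged = True
            break
    L = _kernels.rk4_backward(Y, dt, p, mode, ks, w.A1, w.A2, w.A3, w.T_bar)
    full_uS = bg_S[0::2] + uS * m_S
    full_uD = bg_D[0::2] + uD * m_D
    return ControlSolution(
        t=t,
        u_S=full_uS,
        u_D=full_uD,
        states=Y,
        adjoint=L,
        objective=J,
        converged=converged,
        iterations=pd.DataFrame(log),
        meta=dict(
            update_scheme=update_scheme,
            indicator_mode=pr.indicator_mode,
            opt_u_S=uS * m_S,
            opt_u_D=uD * m_D,
        ),
    )


# -- experiment drivers ----------------------------------------------------

class _ArrayControl:
    """Control defined by linear interpolation of node values."""

    def __init__(self, t: np.ndarray, u: np.ndarray):
        self._t = np.asarray(t, float)
        self._u = np.asarray(u, float)
        self.breakpoints = np.empty(0)

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self._t, self._u))

    def total(self) -> float:
        return float(np.trapezoid(self._u, self._t))

def _truncated_pulse_control(rate: float, period: float, on_time_total: float,
                             horizon: float) -> PulseControl:
    """Pulse train at fixed period whose pulses are sized (last one
    truncated) so the total on-time over the horizon is exact."""
    n = int(np.ceil(horizon / period))
    width = on_time_total / n
    gap = period - width
    if gap < 0:
        raise ValueError("on-time exceeds the horizon at this period")
    starts = np.arange(n) * period
    ctrl = PulseControl(starts, width, rate)
    # handle a final pulse that would overrun: fold the excess into widths
    if starts[-1] + width > horizon:
        full_width = (on_time_total - (horizon - starts[-1])) / (n - 1)
        if full_width > period:
            raise ValueError("cannot fit the requested on-time")
        ctrl = _SplitPulse(starts, full_width, horizon - starts[-1], rate)
    return ctrl


class _SplitPulse(PulseControl):
    """Pulse train whose last pulse has its own width."""

    def __init__(self, starts, width, last_width, rate):
        self.starts = np.sort(np.asarray(starts, float))
        self.h = float(width)
        self.last_width = float(last_width)
        self.rate = float(rate)
        ends = self.starts + self.h
        ends[-1] = self.starts[-1] + self.last_width
        self.breakpoints = np.unique(np.concatenate([self.starts, ends]))

    def __call__(self, t: float) -> float:
        i = np.searchsorted(self.starts, t, side="right") - 1
        if i < 0:
            return 0.0
        width = self.last_width if i == len(self.starts) - 1 else self.h
        return self.rate if t < self.starts[i] + width else 0.0

    def total(self) -> float:
        return self.rate * (self.h * (len(self.starts) - 1) + self.last_width)


# Printed comparison profiles: alternating pulse rates/periods and constant
# rates.  Pulse widths are not printed; they default to values equalizing
# the delivered totals with the constant profiles (IFN-beta on-time 24 of
# 30, DDP on-time 14 of 30).
ALTERNATING_S = dict(rate=5.2344, period=4.0, on_time=24.0)
ALTERNATING_D = dict(rate=53.4109, period=2.0, on_time=14.0)
CONSTANT_S = 4.1875
CONSTANT_D = 24.9251


def run_strategy_I(
    params: ModelParams,
    thresholds: Thresholds | None = None,
    weights: ControlWeights = STRATEGY_I_WEIGHTS,
    *,
    ic: SystemState | None = None,
    n_steps: int = 3000,
    sweep_kwargs: dict | None = None,
) -> dict:
    """Free-horizon optimization of both infusions compared against the
    alternating and constant reference profiles (equal delivered totals).

    Returns a dict with the three solutions/trajectories, their final
    tumour volumes, objectives and delivered totals; ``totals_match``
    flags agreement of the optimal run's totals within 1%.
    """
    from .model import simulate

    thresholds = thresholds or Thresholds()
    if ic is None:
        ic = default_initial_state(params)
    horizon = (weights.t_s, weights.t_e)
    span = weights.t_e - weights.t_s

    alt_S = _truncated_pulse_control(
        ALTERNATING_S["rate"], ALTERNATING_S["period"], ALTERNATING_S["on_time"], span
    )
    alt_D = _truncated_pulse_control(
        ALTERNATING_D["rate"], ALTERNATING_D["period"], ALTERNATING_D["on_time"], span
    )
    const_S = PulseControl([weights.t_s], span, CONSTANT_S)
    const_D = PulseControl([weights.t_s], span, CONSTANT_D)

    runs = {}
    for name, (cS, cD) in (
        ("alternating", (alt_S, alt_D)),
        ("constant", (const_S, const_D)),
    ):
        traj = simulate(params, thresholds, ic, horizon, cS, cD, method="rk4")
        runs[name] = dict(
            trajectory=traj,
            objective=objective(traj, cS, cD, weights),
            final_T=float(traj["T"][-1]),
            total_S=cS.total(),
            total_D=cD.total(),
        )

    problem = ControlProblem(
        params=params,
        thresholds=thresholds,
        ic=ic,
        weights=weights,
        optimize_S=True,
        optimize_D=True,
        n_steps=n_steps,
    )
    # Warm-start from the constant comparison profile: u = 0 sits in the
    # dead zone of the apoptosis switch (no infinitesimal drug effect on
    # the pure tumour cost), so a cold start is stationary-but-useless.
    kw = dict(sweep_kwargs or {})
    kw.setdefault("u_S0", np.full(n_steps + 1, CONSTANT_S))
    kw.setdefault("u_D0", np.full(n_steps + 1, CONSTANT_D))
    sol = forward_backward_sweep(problem, **kw)
    ref_S = runs["constant"]["total_S"]
    ref_D = runs["constant"]["total_D"]
    # evaluate the optimized profile under the sharp-switch model so the
    # three objectives/outcomes are directly comparable
    u_S_opt = _ArrayControl(sol.t, sol.u_S)
    u_D_opt = _ArrayControl(sol.t, sol.u_D)
    traj_opt = simulate(params, thresholds, ic, horizon, u_S_opt, u_D_opt, method="rk4")
    runs["optimal"] = dict(
        solution=sol,
        trajectory=traj_opt,
        objective=objective(traj_opt, u_S_opt, u_D_opt, weights),
        objective_smooth=sol.objective,
        final_T=float(traj_opt["T"][-1]),
        total_S=sol.total_S,
        total_D=sol.total_D,
    )
    runs["totals_match"] = bool(
        abs(sol.total_S - ref_S) <= 0.01 * ref_S
        and abs(sol.total_D - ref_D) <= 0.01 * ref_D
    )
    return runs


def run_strategy_II(
    params: ModelParams,
    scheme: str = "SSSDDD",
    weights: ControlWeights = STRATEGY_II_WEIGHTS,
    *,
    thresholds: Thresholds | None = None,
    ic: SystemState | None = None,
    u_D_rate: float = 46.0,
    slot_length: float = 5.0,
    n_steps: int = 3000,
    sweep_kwargs: dict | None = None,
) -> dict:
    """Optimize the IFN-beta profile on the 'S' slots of ``scheme`` with
    the scheme's DDP pulses held fixed (C2 = C4 = 0: DDP not optimized).

    Returns the solution, the accumulated IFN-beta, and the percent tumour
    reduction at the final time relative to the untreated control."""
    from .model import simulate

    thresholds = thresholds or Thresholds()
    if ic is None:
        ic = default_initial_state(params)
    sched = PulseSchedule(
        sequence=scheme,
        slot_length=slot_length,
        h_s=slot_length,
        h_d=slot_length,
        u_S_rate=0.0,
        u_D_rate=u_D_rate,
        t_start=weights.t_s,
        t_end=weights.t_s + slot_length * len(scheme),
    )
    _, u_D_fixed = build_pulse_controls(sched)
    t = np.linspace(weights.t_s, weights.t_e, n_steps + 1)
    mask_S = np.zeros(n_steps + 1, bool)
    for s in sched.slot_starts("S"):
        mask_S |= (t >= s) & (t < s + slot_length)
    problem = ControlProblem(
        params=params,
        thresholds=thresholds,
        ic=ic,
        weights=weights,
        optimize_S=True,
        optimize_D=False,
        mask_S=mask_S,
        fixed_u_D=u_D_fixed,
        n_steps=n_steps,
    )
    sol = forward_backward_sweep(problem, **(sweep_kwargs or {}))
    ctrl = simulate(
        params, thresholds, ic, (weights.t_s, weights.t_e), method="rk4"
    )
    T_ctrl = float(ctrl["T"][-1])
    # evaluate the optimized profile under the sharp-switch model
    traj = simulate(
        params,
        thresholds,
        ic,
        (weights.t_s, weights.t_e),
        _ArrayControl(sol.t, sol.u_S),
        _ArrayControl(sol.t, sol.u_D),
        method="rk4",
    )
    T_opt = float(traj["T"][-1])
    return dict(
        solution=sol,
        trajectory=traj,
        scheme=scheme,
        accumulated_S=sol.total_S,
        reduction_pct=100.0 * (1.0 - T_opt / T_ctrl),
        final_T=T_opt,
        control_T=T_ctrl,
    )


def half_life_experiment(
    params: ModelParams,
    muS_values: Sequence[float] = (5.5, 4.8, 3.2),
    *,
    thresholds: Thresholds | None = None,
    weights: ControlWeights = STRATEGY_I_WEIGHTS,
    n_steps: int = 3000,
    sweep_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Final tumour volume of the three Strategy-I infusion methods under
    different IFN-beta decay rates (longer half-life = smaller muS)."""
    if np.any(np.asarray(muS_values) <= 0):
        raise ValueError("decay rates must be positive")
    rows = []
    for muS in muS_values:
        p = params.replace(muS=float(muS))
        runs = run_strategy_I(
            p, thresholds, weights, n_steps=n_steps, sweep_kwargs=sweep_kwargs
        )
        for strategy in ("alternating", "constant", "optimal"):
            rows.append(
                dict(muS=float(muS), strategy=strategy, final_T=runs[strategy]["final_T"])
            )
    return pd.DataFrame(rows)
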