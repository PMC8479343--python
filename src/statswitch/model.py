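"""Core dynamical model: STAT1/STAT3/Bcl-2/BAX signalling coupled to
tumour growth under IFN-beta and cisplatin (DDP) infusion.

State vector (dimensionless): S1 (STAT1), S3 (STAT3), B (Bcl-2), X (BAX),
T (tumour volume), S (IFN-beta), J (JAK2), D (DDP).  The intracellular
block has mutual STAT1/STAT3 antagonism through Hill-type autocatalysis,
Bcl-2 driven by STAT3 and repressed by STAT1, and BAX repressed by Bcl-2.
Programmed cell death is a binary switch: tumour cells are killed (and
STAT1 additionally brakes their growth) exactly while Bcl-2 is below B_th
and BAX above X_th.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels
from .params import ModelParams, Thresholds, ReferenceScales, SystemState, STATE_VARS

__all__ = [
    "intracellular_rhs",
    "full_rhs",
    "apoptosis_indicator",
    "classify_phase",
    "Trajectory",
    "simulate",
    "default_initial_state",
    "intracellular_equilibrium_state",
    "nondimensionalize",
    "dimensionalize",
    "ZERO_CONTROL",
]

ZERO_CONTROL = lambda t: 0.0  # noqa: E731 - convenient shared default


def _check_nonneg_finite(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


def intracellular_rhs(
    s1: float,
    s3: float,
    b: float,
    x: float,
    S: float,
    J: float,
    params: ModelParams,
) -> np.ndarray:
    """Time derivatives (dS1, dS3, dB, dX) of the intracellular block at
    fixed IFN-beta level S and JAK2 level J."""
    for name, v in (("s1", s1), ("s3", s3), ("b", b), ("x", x), ("S", S), ("J", J)):
        _check_nonneg_finite(name, v)
    p = params
    dS1 = p.lambda_S1 * S + p.k1 * p.k2**2 / (p.k2**2 + p.alpha * s3**2) - s1
    dS3 = (
        (p.lambda_k + p.lambda_J * J) / (p.K + p.lambda_S2 * S)
        + p.k3 * p.k4**2 / (p.k4**2 + p.beta * s1**2)
        - p.mu3 * s3
    )
    dB = (
        p.lambda1
        + p.k5 * p.k6**2 / (p.k6**2 + p.gamma * s1**2)
        + p.lambda3 * s3
        - p.muB * b
    )
    dX = p.lambda2 + p.k7 * p.k8**2 / (p.k8**2 + p.delta * b**2) - p.muX * x
    return np.array([dS1, dS3, dB, dX])


def apoptosis_indicator(b: float, x: float, thresholds: Thresholds) -> int:
    """1 iff Bcl-2 is strictly below B_th and BAX strictly above X_th."""
    _check_nonneg_finite("b", b)
    _check_nonneg_finite("x", x)
    return int(b < thresholds.B_th and x > thresholds.X_th)


def classify_phase(b: float, x: float, thresholds: Thresholds) -> str:
    """Classify a (Bcl-2, BAX) point as 'Pa' (apoptotic), 'Pt'
    (anti-apoptotic) or 'neither' (strict inequalities in both cases)."""
    _check_nonneg_finite("b", b)
    _check_nonneg_finite("x", x)
    if b < thresholds.B_th and x > thresholds.X_th:
        return "Pa"
    if b > thresholds.B_th and x < thresholds.X_th:
        return "Pt"
    return "neither"


def full_rhs(
    state,
    t: float,
    params: ModelParams,
    thresholds: Thresholds,
    u_S: Callable[[float], float] = ZERO_CONTROL,
    u_D: Callable[[float], float] = ZERO_CONTROL,
) -> np.ndarray:
    """Right-hand side of the full eight-variable system at time t."""
    if not callable(u_S) or not callable(u_D):
        raise TypeError("u_S and u_D must be callables of time")
    y = state.as_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if y.shape != (8,) or not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("state must be 8 finite non-negative values")
    uS = float(u_S(t))
    uD = float(u_D(t))
    if uS < 0 or uD < 0:
        raise ValueError("controls must be non-negative")
    p = _kernels.pack_params(params, thresholds)
    return _kernels.rhs8(y, uS, uD, p, _kernels.SHARP, 0.0)


@dataclass
class Trajectory:
    """Simulation output: time grid, state matrix and indicator column."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 8), columns ordered as STATE_VARS
    indicator: np.ndarray  # {0,1} per time point, recomputed from (B, X)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.states.shape != (len(self.t), 8):
            raise ValueError("states must be (len(t), 8)")

    def __getitem__(self, var: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(var)]

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_array(np.maximum(self.states[-1], 0.0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t", self.t)
        df["indicator"] = self.indicator.astype(int)
        return df

    def to_csv(self, path, **kwargs) -> None:
        self.to_frame().to_csv(path, index=False, **kwargs)


def _control_breakpoints(u, t_span) -> np.ndarray:
    pts = getattr(u, "breakpoints", None)
    if pts is None:
        return np.empty(0)
    pts = np.asarray(pts, float)
    return pts[(pts > t_span[0]) & (pts < t_span[1])]


def _sample_half_grid(u: Callable[[float], float], t: np.ndarray) -> np.ndarray:
    """Sample a control on the half-step grid used by the RK4 kernel."""
    n = len(t) - 1
    th = np.empty(2 * n + 1)
    th[0::2] = t
    th[1::2] = 0.5 * (t[:-1] + t[1:])
    vals = np.fromiter((float(u(tt)) for tt in th), float, count=len(th))
    if np.any(vals < 0):
        raise ValueError("controls must be non-negative")
    return vals


def simulate(
    params: ModelParams,
    thresholds: Thresholds,
    ic: SystemState,
    t_span: tuple[float, float],
    u_S: Callable[[float], float] = ZERO_CONTROL,
    u_D: Callable[[float], float] = ZERO_CONTROL,
    *,
    method: str = "events",
    dt_out: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    rk4_dt: float = 1e-3,
) -> Trajectory:
    """Integrate the full system over ``t_span``.

    method='events' (default): adaptive LSODA restarted at every crossing of
    the two switching surfaces B = B_th and X = X_th and at every control
    breakpoint, so the discontinuous tumour equation is integrated piecewise
    on smooth segments.  method='rk4': fixed-step RK4 (step ``rk4_dt``)
    evaluating the indicator per step; deterministic and fast, used by the
    batch schedule scans.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be non-degenerate")
    if not callable(u_S) or not callable(u_D):
        raise TypeError("u_S and u_D must be callables of time")
    y0 = ic.as_array() if isinstance(ic, SystemState) else np.asarray(ic, float)
    if y0.shape != (8,) or np.any(y0 < 0) or not np.all(np.isfinite(y0)):
        raise ValueError("initial condition must be 8 finite non-negative values")
    p = _kernels.pack_params(params, thresholds)
    B_th, X_th = thresholds.B_th, thresholds.X_th

    if method == "rk4":
        n = max(2, int(round((t1 - t0) / rk4_dt)))
        t = np.linspace(t0, t1, n + 1)
        uS_half = _sample_half_grid(u_S, t)
        uD_half = _sample_half_grid(u_D, t)
        Y = _kernels.rk4_forward(y0, uS_half, uD_half, t[1] - t[0], p, _kernels.SHARP, 0.0)
        stride = max(1, int(round(dt_out / (t[1] - t[0]))))
        idx = np.unique(np.r_[np.arange(0, n + 1, stride), n])
        ind = ((Y[idx, 2] < B_th) & (Y[idx, 3] > X_th)).astype(float)
        return Trajectory(t[idx], Y[idx], ind, meta={"method": "rk4", "dt": rk4_dt})
    if method != "events":
        raise ValueError(f"unknown method {method!r}")

    # breakpoints from pulsed controls; switching surfaces handled by events
    brk = np.unique(
        np.concatenate(
            [[t0, t1], _control_breakpoints(u_S, (t0, t1)), _control_breakpoints(u_D, (t0, t1))]
        )
    )

    def rhs(t, y):
        return _kernels.rhs8(np.maximum(y, 0.0), float(u_S(t)), float(u_D(t)), p, _kernels.SHARP, 0.0)

    def make_events(y):
        # watch only for crossings AWAY from the current side of each
        # switching surface, so a restart at the surface cannot refire
        ev_B = lambda t, yy: yy[2] - B_th  # noqa: E731
        ev_X = lambda t, yy: yy[3] - X_th  # noqa: E731
        ev_B.terminal = ev_X.terminal = True
        ev_B.direction = -1.0 if y[2] >= B_th else 1.0
        ev_X.direction = -1.0 if y[3] >= X_th else 1.0
        return [ev_B, ev_X]

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    restarts = 0
    y = y0.copy()
    for a, b in zip(brk[:-1], brk[1:]):
        tcur = a
        while tcur < b - 1e-12:
            grid = np.arange(tcur, b, dt_out)
            grid = np.append(grid[grid > tcur + 1e-12], b)
            events = make_events(y)
            sol = solve_ivp(
                rhs,
                (tcur, b),
                y,
                method="LSODA",
                t_eval=grid,
                events=events,
                rtol=rtol,
                atol=atol,
                max_step=(b - tcur),
            )
            if not sol.success:
                raise RuntimeError(f"solver failed near t={sol.t[-1] if len(sol.t) else tcur}")
            if len(sol.t):
                ts.append(sol.t)
                ys.append(sol.y.T)
            if sol.status == 1:  # event: restart just past the crossing
                fired = [i for i, te in enumerate(sol.t_events) if len(te)]
                k = min(fired, key=lambda i: sol.t_events[i][0])
                tev = sol.t_events[k][0]
                yev = np.asarray(sol.y_events[k][0], float)
                tcur = tev + 1e-9
                y = np.maximum(yev, 0.0)
                # place the crossing variable strictly on its new side so
                # the restarted integration cannot refire the same event
                # (the switch does not feed back on B or X, so this 1e-9
                # nudge is dynamically inert)
                idx, level = (2, B_th) if k == 0 else (3, X_th)
                y[idx] = level + events[k].direction * 1e-9
                restarts += 1
                if restarts > 10_000:
                    raise RuntimeError(f"event chatter at t={tev}")
            else:
                tcur = b
                y = np.maximum(sol.y[:, -1], 0.0)
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=0)
    keep = np.r_[True, np.diff(t) > 1e-12]
    t, Y = t[keep], Y[keep]
    ind = ((Y[:, 2] < B_th) & (Y[:, 3] > X_th)).astype(float)
    return Trajectory(t, Y, ind, meta={"method": "events", "restarts": restarts})


def intracellular_equilibrium_state(
    params: ModelParams, S: float = 0.0, J: float | None = None
) -> np.ndarray:
    """Anti-apoptotic (lowest-STAT1) intracellular equilibrium at fixed S, J.

    The Bcl-2 and BAX equations are slaved to (S1, S3) and S3 is an explicit
    function of S1 at equilibrium, so equilibria reduce to roots of a scalar
    function of S1; the smallest root is the anti-apoptotic branch.
    """
    if J is None:
        J = params.Js / params.muJ
    p = params

    def s3_of(s1):
        return (p.lambda_k + p.lambda_J * J) / (p.K + p.lambda_S2 * S) / p.mu3 + (
            p.k3 * p.k4**2 / (p.k4**2 + p.beta * s1**2)
        ) / p.mu3

    def h(s1):
        s3 = s3_of(s1)
        return p.lambda_S1 * S + p.k1 * p.k2**2 / (p.k2**2 + p.alpha * s3**2) - s1

    grid = np.linspace(0.0, 25.0, 2501)
    hv = np.array([h(s) for s in grid])
    sign_change = np.where(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError("no intracellular equilibrium found in [0, 25]")
    i = sign_change[0]
    s1 = brentq(h, grid[i], grid[i + 1], xtol=1e-12)
    s3 = s3_of(s1)
    b = (
        p.lambda1 + p.k5 * p.k6**2 / (p.k6**2 + p.gamma * s1**2) + p.lambda3 * s3
    ) / p.muB
    x = (p.lambda2 + p.k7 * p.k8**2 / (p.k8**2 + p.delta * b**2)) / p.muX
    return np.array([s1, s3, b, x])


def default_initial_state(
    params: ModelParams, T0_init: float = 0.1
) -> SystemState:
    """Default protocol: intracellular variables at the anti-apoptotic
    equilibrium for S=0 and baseline JAK2 (J = Js/muJ); no drug on board;
    tumour volume ``T0_init`` (default 0.1, i.e. 0.1% of carrying capacity,
    matching an untreated volume of about 3.53 at t=30)."""
    s1, s3, b, x = intracellular_equilibrium_state(params, S=0.0)
    return SystemState(s1, s3, b, x, T0_init, 0.0, params.Js / params.muJ, 0.0)


def nondimensionalize(values, scales: ReferenceScales):
    """Map dimensional state values (ordered as STATE_VARS) to model units."""
    v = np.asarray(values, dtype=float)
    return v / scales.as_state_vector()


def dimensionalize(values, scales: ReferenceScales):
    """Inverse of :func:`nondimensionalize`."""
    v = np.asarray(values, dtype=float)
    return v * scales.as_state_vector()


def nondimensionalize_time(t_dim, scales: ReferenceScales):
    """Dimensional time -> model time (t = mu_S1_dim * t_dim)."""
    return np.asarray(t_dim, float) * scales.mu_S1_dim


def dimensionalize_time(t, scales: ReferenceScales):
    return np.asarray(t, float) / scales.mu_S1_dim
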