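"""Equilibria, stability and bistability analysis of the intracellular
subsystem at fixed IFN-beta (S) and JAK2 (J) levels.

The four-variable block (S1, S3, B, X) has at most three equilibria for
the default parameters: an anti-apoptotic branch (low STAT1), an apoptotic
branch (high STAT1) and, inside the bistable window of S, an unstable
middle branch.  The two saddle-node (fold) points bounding the window are
located by bisection on the equilibrium count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, root
from scipy.stats import qmc

from .model import classify_phase, intracellular_rhs
from .params import ModelParams, Thresholds

__all__ = [
    "Equilibrium",
    "BifurcationDiagram",
    "find_equilibria",
    "scan_S",
    "bistability_window",
    "hysteresis_sweep",
    "calibrate_source_coefficients",
    "calibrate_to_anchors",
    "intracellular_jacobian",
]

_STAB_TOL = 1e-8


@dataclass(frozen=True)
class Equilibrium:
    S1: float
    S3: float
    B: float
    X: float
    stable: bool
    leading_eig: float  # largest real part of the 4x4 Jacobian spectrum
    phase: str  # 'Pt' | 'Pa' | 'neither'

    @property
    def point(self) -> np.ndarray:
        return np.array([self.S1, self.S3, self.B, self.X])


@dataclass
class BifurcationDiagram:
    S: np.ndarray
    equilibria: list  # list of lists of Equilibrium, one list per S value
    S_m: float | None = None  # lower fold (refined)
    S_M: float | None = None  # upper fold (refined)
    meta: dict = field(default_factory=dict)

    def counts(self) -> np.ndarray:
        return np.array([len(e) for e in self.equilibria])

    def branches(self) -> "np.ndarray":
        """Branch label per equilibrium by S1 ordering: 0 lower, 1 middle,
        2 upper (single equilibria are labelled by phase side)."""
        labels = []
        for eqs in self.equilibria:
            order = np.argsort([e.S1 for e in eqs])
            lab = np.empty(len(eqs), int)
            if len(eqs) == 3:
                lab[order] = [0, 1, 2]
            else:
                lab[:] = 0 if (len(eqs) and eqs[0].phase != "Pa") else 2
            labels.append(lab)
        return np.array(labels, dtype=object)

    def to_frame(self):
        import pandas as pd

        rows = []
        for S, eqs, labs in zip(self.S, self.equilibria, self.branches()):
            for e, lab in zip(eqs, np.atleast_1d(labs)):
                rows.append(
                    dict(S=S, branch=int(lab), S1=e.S1, S3=e.S3, B=e.B, X=e.X,
                         stable=e.stable, leading_eig=e.leading_eig, phase=e.phase)
                )
        return pd.DataFrame(rows)


def intracellular_jacobian(point, S: float, J: float, params: ModelParams) -> np.ndarray:
    """Analytic 4x4 Jacobian of the intracellular block."""
    s1, s3, b, x = point
    p = params
    Jm = np.zeros((4, 4))
    d1 = p.k2**2 + p.alpha * s3**2
    Jm[0, 0] = -1.0
    Jm[0, 1] = -2.0 * p.alpha * s3 * p.k1 * p.k2**2 / d1**2
    d2 = p.k4**2 + p.beta * s1**2
    Jm[1, 0] = -2.0 * p.beta * s1 * p.k3 * p.k4**2 / d2**2
    Jm[1, 1] = -p.mu3
    d3 = p.k6**2 + p.gamma * s1**2
    Jm[2, 0] = -2.0 * p.gamma * s1 * p.k5 * p.k6**2 / d3**2
    Jm[2, 1] = p.lambda3
    Jm[2, 2] = -p.muB
    d4 = p.k8**2 + p.delta * b**2
    Jm[3, 2] = -2.0 * p.delta * b * p.k7 * p.k8**2 / d4**2
    Jm[3, 3] = -p.muX
    return Jm


def _make_equilibrium(point, S, J, params, thresholds) -> Equilibrium:
    eigs = np.linalg.eigvals(intracellular_jacobian(point, S, J, params))
    lead = float(np.max(eigs.real))
    if lead < -_STAB_TOL:
        stable = True
    elif lead > _STAB_TOL:
        stable = False
    else:
        stable = False  # marginal: flagged via leading_eig ~ 0
    phase = classify_phase(max(point[2], 0.0), max(point[3], 0.0), thresholds)
    return Equilibrium(*point, stable=stable, leading_eig=lead, phase=phase)


def find_equilibria(
    params: ModelParams,
    S: float,
    J: float,
    thresholds: Thresholds | None = None,
    *,
    box: tuple[float, float] = (0.0, 20.0),
    n_starts: int = 48,
    seed: int = 0,
    dedup_tol: float = 1e-6,
) -> list[Equilibrium]:
    """All equilibria of the intracellular block in ``box``^4, found by
    multi-start root finding from a Latin-hypercube of initial guesses,
    deduplicated and tagged with linear stability."""
    if S < 0 or J < 0:
        raise ValueError("S and J must be non-negative")
    thresholds = thresholds or Thresholds()

    def fun(v):
        v = np.maximum(v, 0.0)
        return intracellular_rhs(*v, S, J, params)

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), [box[0]] * 4, [box[1]] * 4)
    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = root(fun, x0, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        pt = np.maximum(sol.x, 0.0)
        if np.max(np.abs(fun(pt))) > 1e-8:
            continue
        if np.any(pt > box[1] + 1e-6):
            continue
        if not any(np.linalg.norm(pt - q) < dedup_tol for q in roots):
            roots.append(pt)
    if not roots:
        warnings.warn(f"no equilibrium found at S={S}, J={J}")
        return []
    roots.sort(key=lambda q: q[0])
    return [_make_equilibrium(pt, S, J, params, thresholds) for pt in roots]


def _count(params, S, J, **kw) -> int:
    return len(find_equilibria(params, S, J, **kw))


def scan_S(
    params: ModelParams,
    S_grid: Sequence[float],
    J: float,
    thresholds: Thresholds | None = None,
    *,
    refine_tol: float = 1e-4,
    n_starts: int = 48,
) -> BifurcationDiagram:
    """Bifurcation diagram over an increasing grid of IFN-beta levels, with
    fold points refined by bisection on the equilibrium count."""
    S_grid = np.asarray(S_grid, float)
    if np.any(np.diff(S_grid) <= 0):
        raise ValueError("S_grid must be strictly increasing")
    thresholds = thresholds or Thresholds()
    eqs = [
        find_equilibria(params, S, J, thresholds, n_starts=n_starts) for S in S_grid
    ]
    diagram = BifurcationDiagram(S_grid, eqs, meta={"J": J})
    counts = diagram.counts()
    multi = np.where(counts == 3)[0]
    if len(multi) and len(S_grid) > 1:
        kw = dict(n_starts=n_starts)

        def cnt(S):
            return _count(params, S, J, **kw)

        i0, i1 = multi[0], multi[-1]
        if i0 > 0:
            diagram.S_m = brentq(
                lambda S: cnt(S) - 2, S_grid[i0 - 1], S_grid[i0], xtol=refine_tol
            )
        else:
            diagram.S_m = float(S_grid[0])
        if i1 < len(S_grid) - 1:
            diagram.S_M = brentq(
                lambda S: cnt(S) - 2, S_grid[i1], S_grid[i1 + 1], xtol=refine_tol
            )
        else:
            diagram.S_M = float(S_grid[-1])
    return diagram


def bistability_window(diagram: BifurcationDiagram):
    """[S_m, S_M] where three equilibria coexist, or None if monostable."""
    if diagram.S_m is not None and diagram.S_M is not None:
        return (diagram.S_m, diagram.S_M)
    counts = diagram.counts()
    multi = np.where(counts == 3)[0]
    if len(multi) == 0:
        return None
    return (float(diagram.S[multi[0]]), float(diagram.S[multi[-1]]))


def hysteresis_sweep(
    params: ModelParams,
    J: float,
    S_path: tuple[float, float] = (0.0, 1.0),
    *,
    rate: float = 2e-5,
    thresholds: Thresholds | None = None,
):
    """Slow triangular ramp of S (up then down) through the intracellular
    dynamics; returns the S values at which the phase switches.

    The ramp must be slow relative to the O(1) relaxation times; with the
    default rate the detected transitions track the fold points to ~1e-2.
    """
    from scipy.integrate import solve_ivp

    thresholds = thresholds or Thresholds()
    S_lo, S_hi = S_path
    if rate <= 0:
        raise ValueError("rate must be positive")
    span = (S_hi - S_lo) / rate
    p = params
    c_S3 = (p.lambda_k + p.lambda_J * J)

    def make_rhs(direction):
        def rhs(t, y):
            S = S_lo + rate * t if direction > 0 else S_hi - rate * t
            s1, s3, b, x = np.maximum(y, 0.0)
            return (
                p.lambda_S1 * S + p.k1 * p.k2**2 / (p.k2**2 + p.alpha * s3**2) - s1,
                c_S3 / (p.K + p.lambda_S2 * S)
                + p.k3 * p.k4**2 / (p.k4**2 + p.beta * s1**2)
                - p.mu3 * s3,
                p.lambda1
                + p.k5 * p.k6**2 / (p.k6**2 + p.gamma * s1**2)
                + p.lambda3 * s3
                - p.muB * b,
                p.lambda2 + p.k7 * p.k8**2 / (p.k8**2 + p.delta * b**2) - p.muX * x,
            )

        return rhs

    def cross(t, y):
        return y[2] - thresholds.B_th

    cross.terminal = False

    transitions = {}
    from .model import intracellular_equilibrium_state

    y_end = intracellular_equilibrium_state(params, S=S_lo, J=J)
    for direction, key in ((+1, "up"), (-1, "down")):
        sol = solve_ivp(
            make_rhs(direction),
            (0.0, span),
            y_end,
            method="LSODA",
            events=cross,
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError("hysteresis ramp integration failed")
        tev = sol.t_events[0]
        if len(tev):
            S_at = S_lo + rate * tev[0] if direction > 0 else S_hi - rate * tev[0]
            transitions[key] = float(S_at)
        else:
            transitions[key] = None
        y_end = sol.y[:, -1]
    return transitions


def calibrate_source_coefficients(
    params: ModelParams,
    target_window: tuple[float, float] = (0.3, 0.53),
    *,
    bracket: tuple[float, float] = (0.5, 2.0),
    J: float = 0.0,
    grid_step: float = 0.01,
    tol: float = 1e-3,
) -> tuple[float, tuple[float, float]]:
    """Scalar calibration of the IFN-beta -> STAT1 source coefficient.

    Searches lambda_S1 in ``bracket`` (lambda_S2 held fixed) minimising the
    maximum deviation of the two fold points from ``target_window``.
    Returns (lambda_S1, achieved_window); raises if no value in the bracket
    yields bistability.
    """
    lo, hi = target_window
    if not (0 <= lo < hi <= 1):
        raise ValueError("target window must lie within [0, 1]")

    def window_at(lam):
        p = params.replace(lambda_S1=lam)
        grid = np.arange(max(grid_step, lo - 0.2), min(1.0, hi + 0.25), grid_step)
        d = scan_S(p, grid, J, n_starts=24)
        return bistability_window(d)

    def maxdev(lam):
        w = window_at(lam)
        if w is None:
            return np.inf
        return max(abs(w[0] - lo), abs(w[1] - hi))

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        maxdev, bounds=bracket, method="bounded", options={"xatol": tol}
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("calibration failure: no bistability in the bracket")
    achieved = window_at(res.x)
    return float(res.x), achieved


def calibrate_to_anchors(
    params: ModelParams,
    *,
    fold_targets: tuple[float, float] = (0.3, 0.53),
    boundary_S: float = 1.0,
    thresholds: Thresholds | None = None,
    x0: tuple[float, float] = (0.95, 4.0),
) -> tuple[float, float]:
    """Joint minimax calibration of (lambda_S1, lambda_S2) to the three
    structural anchors: the two J=0 fold points and the IFN-beta level at
    which the J=1 branch crosses the apoptosis boundary (target
    ``boundary_S``).  This is how the package defaults were produced."""
    from scipy.optimize import minimize

    thresholds = thresholds or Thresholds()

    def onset(p):
        # S where the (unique) J=1 branch's Bcl-2 value crosses B_th
        def b_of(S):
            from .model import intracellular_equilibrium_state

            return intracellular_equilibrium_state(p, S=S, J=1.0)[2] - thresholds.B_th

        return brentq(b_of, 0.2, 4.0, xtol=1e-5)

    def devs(v):
        p = params.replace(lambda_S1=float(v[0]), lambda_S2=float(v[1]))
        grid = np.arange(0.02, 1.0, 0.02)
        w = bistability_window(scan_S(p, grid, 0.0, n_starts=24))
        if w is None:
            return 10.0
        try:
            c = onset(p)
        except ValueError:
            return 10.0
        return max(
            abs(w[0] - fold_targets[0]),
            abs(w[1] - fold_targets[1]),
            abs(c - boundary_S),
        )

    res = minimize(devs, x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-5})
    return float(res.x[0]), float(res.x[1])
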