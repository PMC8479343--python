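"""Pulsed infusion schedules of IFN-beta ('S') and cisplatin ('D') and the
schedule experiments: dose response, best/worst injection orders, minimum
dose and maximum resting time for a 50% tumour reduction.

A schedule is a string over {S, D}; each character owns one slot of length
``slot_length`` on the horizon, and the drug is infused at a constant rate
for the first ``h_s`` (resp. ``h_d``) time units of its slot.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import Trajectory, default_initial_state, simulate
from .params import ModelParams, SystemState, Thresholds

__all__ = [
    "PulseSchedule",
    "PulseControl",
    "build_pulse_controls",
    "enumerate_schedules",
    "simulate_schedule",
    "dose_response",
    "min_rate_for_reduction",
    "max_resting_time",
    "rescale_rate_for_fixed_total",
    "grouped_schedule_summary",
    "schedule_scan",
]


@dataclass(frozen=True)
class PulseSchedule:
    """An ordered drug sequence with slot geometry and infusion rates."""

    sequence: str
    slot_length: float = 5.0
    h_s: float = 5.0
    h_d: float = 5.0
    u_S_rate: float = 8.2
    u_D_rate: float = 46.0
    t_start: float = 0.0
    t_end: float = 30.0

    def __post_init__(self) -> None:
        if set(self.sequence) - {"S", "D"}:
            raise ValueError("sequence must use only 'S' and 'D'")
        if self.h_s > self.slot_length or self.h_d > self.slot_length:
            raise ValueError("infusion durations cannot exceed the slot length")
        if min(self.h_s, self.h_d, self.slot_length) <= 0:
            raise ValueError("durations must be positive")
        if self.u_S_rate < 0 or self.u_D_rate < 0:
            raise ValueError("rates must be non-negative")
        if not self.t_end > self.t_start:
            raise ValueError("horizon must have positive length")

    @property
    def N_S(self) -> int:
        return self.sequence.count("S")

    @property
    def N_D(self) -> int:
        return self.sequence.count("D")

    def slot_starts(self, drug: str) -> np.ndarray:
        return np.array(
            [
                self.t_start + i * self.slot_length
                for i, c in enumerate(self.sequence)
                if c == drug
            ]
        )

    def total_dose(self, drug: str = "S") -> float:
        if drug == "S":
            return self.N_S * self.h_s * self.u_S_rate
        return self.N_D * self.h_d * self.u_D_rate

    def replace(self, **changes) -> "PulseSchedule":
        return replace(self, **changes)


class PulseControl:
    """Piecewise-constant control: ``rate`` on [t_i, t_i + h) for each pulse
    start t_i, zero elsewhere; exposes its breakpoints for the integrator."""

    def __init__(self, starts: Sequence[float], h: float, rate: float):
        self.starts = np.sort(np.asarray(starts, float))
        self.h = float(h)
        self.rate = float(rate)
        self.breakpoints = np.unique(
            np.concatenate([self.starts, self.starts + self.h])
        )

    def __call__(self, t: float) -> float:
        if self.rate == 0.0 or len(self.starts) == 0:
            return 0.0
        i = np.searchsorted(self.starts, t, side="right") - 1
        if i >= 0 and t < self.starts[i] + self.h:
            return self.rate
        return 0.0

    def total(self) -> float:
        return len(self.starts) * self.h * self.rate


def build_pulse_controls(schedule: PulseSchedule):
    """(u_S, u_D) pulse-train controls for a schedule."""
    u_S = PulseControl(schedule.slot_starts("S"), schedule.h_s, schedule.u_S_rate)
    u_D = PulseControl(schedule.slot_starts("D"), schedule.h_d, schedule.u_D_rate)
    return u_S, u_D


def enumerate_schedules(N_S: int, N_D: int) -> list[str]:
    """All distinct orderings of N_S 'S' and N_D 'D' slots, sorted."""
    if N_S < 0 or N_D < 0:
        raise ValueError("counts must be non-negative")
    return sorted(set("".join(p) for p in permutations("S" * N_S + "D" * N_D)))


def simulate_schedule(
    params: ModelParams,
    thresholds: Thresholds,
    ic: SystemState | None,
    schedule: PulseSchedule,
    *,
    control: str = "no_ifn",
    method: str = "rk4",
    rk4_dt: float = 1e-3,
) -> tuple[Trajectory, float]:
    """Simulate a schedule and return (trajectory, normalized final volume).

    ``control`` selects the reference run for the normalization:
    'no_ifn'    — same DDP pulses, u_S = 0 (the 50%-reduction convention);
    'untreated' — both controls zero.
    """
    if control not in ("no_ifn", "untreated"):
        raise ValueError("control must be 'no_ifn' or 'untreated'")
    if ic is None:
        ic = default_initial_state(params)
    u_S, u_D = build_pulse_controls(schedule)
    span = (schedule.t_start, schedule.t_end)
    traj = simulate(
        params, thresholds, ic, span, u_S, u_D, method=method, rk4_dt=rk4_dt
    )
    ctrl_sched = schedule.replace(u_S_rate=0.0) if control == "no_ifn" else schedule.replace(
        u_S_rate=0.0, u_D_rate=0.0
    )
    c_S, c_D = build_pulse_controls(ctrl_sched)
    ctrl = simulate(
        params, thresholds, ic, span, c_S, c_D, method=method, rk4_dt=rk4_dt
    )
    T_end = traj["T"][-1]
    T_ctrl = ctrl["T"][-1]
    return traj, float(T_end / T_ctrl)


def _final_volume(params, thresholds, ic, schedule, method, rk4_dt) -> float:
    u_S, u_D = build_pulse_controls(schedule)
    traj = simulate(
        params,
        thresholds,
        ic,
        (schedule.t_start, schedule.t_end),
        u_S,
        u_D,
        method=method,
        rk4_dt=rk4_dt,
    )
    return float(traj["T"][-1])


def _normalized_volume(params, thresholds, ic, schedule, method="rk4", rk4_dt=1e-3):
    treated = _final_volume(params, thresholds, ic, schedule, method, rk4_dt)
    ctrl = _final_volume(
        params, thresholds, ic, schedule.replace(u_S_rate=0.0), method, rk4_dt
    )
    return treated / ctrl


def dose_response(
    params: ModelParams,
    thresholds: Thresholds | None = None,
    *,
    pulse_times: Sequence[float] = (1.0, 3.0, 5.0, 7.0, 9.0),
    h_s: float = 2.0,
    u_S_grid: Sequence[float] = (0, 2, 4, 6, 8, 10, 15, 20, 40, 60, 100),
    eval_time: float = 25.0,
    ic: SystemState | None = None,
    rk4_dt: float = 1e-3,
) -> pd.DataFrame:
    """Tumour volume at ``eval_time`` versus IFN-beta infusion rate for a
    fixed pulse train (the periodic-injection dose-response experiment)."""
    thresholds = thresholds or Thresholds()
    if ic is None:
        ic = default_initial_state(params)
    if np.any(np.asarray(u_S_grid) < 0):
        raise ValueError("rates must be non-negative")
    rows = []
    for u in u_S_grid:
        u_S = PulseControl(pulse_times, h_s, float(u))
        traj = simulate(
            params,
            thresholds,
            ic,
            (0.0, eval_time),
            u_S,
            method="rk4",
            rk4_dt=rk4_dt,
        )
        rows.append(dict(u_S=float(u), T_eval=float(traj["T"][-1])))
    return pd.DataFrame(rows)


def min_rate_for_reduction(
    params: ModelParams,
    thresholds: Thresholds,
    schedule: PulseSchedule,
    *,
    target_fraction: float = 0.5,
    bracket: tuple[float, float] = (0.5, 30.0),
    ic: SystemState | None = None,
    xtol: float = 1e-3,
    rk4_dt: float = 1e-3,
) -> tuple[float, float]:
    """Minimal IFN-beta rate whose normalized final volume reaches
    ``target_fraction`` of the no-IFN-beta control, by bisection on the
    rate.  Returns (rate, total dose = N_S * h_s * rate)."""
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    if ic is None:
        ic = default_initial_state(params)

    def excess(u):
        nv = _normalized_volume(
            params, thresholds, ic, schedule.replace(u_S_rate=float(u)), rk4_dt=rk4_dt
        )
        return nv - target_fraction

    lo, hi = bracket
    flo, fhi = excess(lo), excess(hi)
    for _ in range(4):  # bracket auto-expansion
        if flo * fhi <= 0:
            break
        hi *= 2.0
        fhi = excess(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"bracket does not straddle the target: f({lo})={flo:.4f}, f({hi})={fhi:.4f}"
        )
    rate = brentq(excess, lo, hi, xtol=xtol)
    return float(rate), float(schedule.N_S * schedule.h_s * rate)


def max_resting_time(
    params: ModelParams,
    thresholds: Thresholds,
    schedule: PulseSchedule,
    *,
    target_fraction: float = 0.5,
    ic: SystemState | None = None,
    xtol: float = 1e-3,
    h_min: float = 0.02,
    rk4_dt: float = 1e-3,
) -> tuple[float, bool]:
    """Maximum per-slot resting time (slot_length - h_s) still achieving the
    target reduction at the schedule's fixed IFN-beta rate, by bisection on
    the infusion duration h_s.  Returns (resting time, achieved flag);
    (0.0, False) when even continuous infusion misses the target."""
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if target_fraction == 1.0:
        return float(schedule.slot_length), True
    if ic is None:
        ic = default_initial_state(params)

    def excess(h):
        nv = _normalized_volume(
            params, thresholds, ic, schedule.replace(h_s=float(h)), rk4_dt=rk4_dt
        )
        return nv - target_fraction

    full = excess(schedule.slot_length)
    if full > 0:
        return 0.0, False
    if excess(h_min) <= 0:
        return float(schedule.slot_length - h_min), True
    h_star = brentq(excess, h_min, schedule.slot_length, xtol=xtol)
    return float(schedule.slot_length - h_star), True


def rescale_rate_for_fixed_total(
    schedule: PulseSchedule, total_dose: float, drug: str = "S"
) -> PulseSchedule:
    """Rate such that N * h * rate equals ``total_dose`` for the drug."""
    if drug == "S":
        n, h = schedule.N_S, schedule.h_s
        key = "u_S_rate"
    elif drug == "D":
        n, h = schedule.N_D, schedule.h_d
        key = "u_D_rate"
    else:
        raise ValueError("drug must be 'S' or 'D'")
    if n * h <= 0:
        raise ValueError("schedule has zero infusion time for this drug")
    return schedule.replace(**{key: total_dose / (n * h)})


def schedule_scan(
    params: ModelParams,
    thresholds: Thresholds,
    base: PulseSchedule,
    *,
    ic: SystemState | None = None,
    control: str = "no_ifn",
    rk4_dt: float = 1e-3,
) -> pd.DataFrame:
    """Run every ordering of the base schedule's S/D slots; returns one row
    per sequence with the normalized final volume and time-averaged
    intracellular levels."""
    if ic is None:
        ic = default_initial_state(params)
    rows = []
    for seq in enumerate_schedules(base.N_S, base.N_D):
        sched = base.replace(sequence=seq)
        traj, nv = simulate_schedule(
            params, thresholds, ic, sched, control=control, rk4_dt=rk4_dt
        )
        t = traj.t
        means = {
            v: float(np.trapezoid(traj[v], t) / (t[-1] - t[0]))
            for v in ("S1", "S3", "B", "X")
        }
        rows.append(
            dict(
                sequence=seq,
                u_S=sched.u_S_rate,
                u_D=sched.u_D_rate,
                h_s=sched.h_s,
                h_d=sched.h_d,
                normalized_volume=nv,
                total_dose_S=sched.total_dose("S"),
                total_dose_D=sched.total_dose("D"),
                **{f"mean_{k}": v for k, v in means.items()},
            )
        )
    return pd.DataFrame(rows)


def grouped_schedule_summary(
    results: pd.DataFrame, grouping: str = "first-drug"
) -> pd.DataFrame:
    """Group means of the signalling levels and tumour volume across a
    schedule scan.

    grouping='first-drug': schedules starting with IFN-beta versus DDP.
    grouping='first-half-weighting': schedules with more IFN-beta slots in
    the first half of the horizon versus the rest.
    """
    req = {"sequence", "normalized_volume", "mean_S1", "mean_S3", "mean_B", "mean_X"}
    if not req <= set(results.columns):
        raise ValueError(f"results missing columns {sorted(req - set(results.columns))}")
    if grouping == "first-drug":
        key = results["sequence"].str[0].map({"S": "IFN-first", "D": "DDP-first"})
    elif grouping == "first-half-weighting":
        def first_half_s(seq):
            half = len(seq) // 2
            return seq[:half].count("S") > seq[half:].count("S")

        key = results["sequence"].map(
            lambda s: "IFN-weighted-first-half" if first_half_s(s) else "IFN-weighted-second-half"
        )
    else:
        raise ValueError("grouping must be 'first-drug' or 'first-half-weighting'")
    grouped = results.groupby(key)[
        ["mean_S1", "mean_S3", "mean_B", "mean_X", "normalized_volume"]
    ].mean()
    if (results.groupby(key).size() == 0).any() or len(grouped) == 0:
        raise ValueError("empty group")
    return grouped
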