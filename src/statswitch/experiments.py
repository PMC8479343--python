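"""Experiment configuration, fixtures and reproducible experiment runs.

Each named experiment reproduces one analysis of the study: the
equilibrium/bifurcation analyses (fig3-fig5), the infusion-schedule
experiments (fig6-fig9) and the optimal-control comparisons (fig10-fig12).
A config is a YAML or JSON mapping validated against a strict schema;
omitted model parameters fall back to the packaged defaults.  Every output
carries a provenance header (package version + config hash).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bifurcation import bistability_window, find_equilibria, scan_S
from .dosing import (
    PulseSchedule,
    dose_response,
    max_resting_time,
    min_rate_for_reduction,
    rescale_rate_for_fixed_total,
    schedule_scan,
    grouped_schedule_summary,
)
from .model import default_initial_state, simulate
from .optimal_control import (
    ControlWeights,
    STRATEGY_I_WEIGHTS,
    STRATEGY_II_WEIGHTS,
    half_life_experiment,
    run_strategy_I,
    run_strategy_II,
)
from .dosing import PulseControl
from .params import ModelParams, Thresholds

__all__ = ["ExperimentConfig", "load_config", "run_experiment", "EXPERIMENTS"]

EXPERIMENTS = (
    "fig3", "fig4", "fig5", "fig6", "fig7", "fig8", "fig9",
    "fig10", "fig11", "fig12", "custom",
)

_PARAM_KEYS = {f.name for f in dc_fields(ModelParams)}
_THRESH_KEYS = {f.name for f in dc_fields(Thresholds)}
_SCHEDULE_KEYS = {
    "sequence", "slot_length", "h_s", "h_d", "u_S_rate", "u_D_rate",
    "t_start", "t_end",
}
_WEIGHT_KEYS = {"A1", "A2", "A3", "C1", "C2", "C3", "C4", "T_bar", "t_s", "t_e"}
_SOLVER_KEYS = {"method", "rk4_dt", "n_steps", "rtol", "atol", "scan_step"}
_TOP_KEYS = {
    "experiment", "params", "thresholds", "schedule", "weights",
    "solver", "output_dir", "seed", "T_init", "strategy", "scheme",
}


@dataclass
class ExperimentConfig:
    experiment: str = "custom"
    params: ModelParams = field(default_factory=ModelParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    schedule: PulseSchedule | None = None
    weights: ControlWeights | None = None
    solver: dict = field(default_factory=dict)
    output_dir: str = "results"
    seed: int | None = None
    T_init: float = 0.1
    strategy: str | None = None
    scheme: str = "SSSDDD"
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @property
    def provenance(self) -> str:
        return f"statswitch {__version__} experiment={self.experiment} config={self.config_hash()}"


def _check_numeric(block: str, mapping: dict) -> None:
    for k, v in mapping.items():
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            if block == "schedule" and k == "sequence":
                continue
            raise ValueError(f"config key {block}.{k} must be numeric, got {v!r}")


def _build(data: dict) -> ExperimentConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    exp = data.get("experiment", "custom")
    if exp not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {exp!r}; valid names: {EXPERIMENTS}")
    p_over = dict(data.get("params") or {})
    if set(p_over) - _PARAM_KEYS:
        raise ValueError(f"unknown model parameters: {sorted(set(p_over) - _PARAM_KEYS)}")
    _check_numeric("params", p_over)
    th_over = dict(data.get("thresholds") or {})
    if set(th_over) - _THRESH_KEYS:
        raise ValueError(f"unknown thresholds: {sorted(set(th_over) - _THRESH_KEYS)}")
    _check_numeric("thresholds", th_over)
    sched = None
    if data.get("schedule"):
        s_over = dict(data["schedule"])
        if set(s_over) - _SCHEDULE_KEYS:
            raise ValueError(f"unknown schedule keys: {sorted(set(s_over) - _SCHEDULE_KEYS)}")
        _check_numeric("schedule", s_over)
        sched = PulseSchedule(**s_over)
    wts = None
    if data.get("weights"):
        w_over = dict(data["weights"])
        if set(w_over) - _WEIGHT_KEYS:
            raise ValueError(f"unknown weight keys: {sorted(set(w_over) - _WEIGHT_KEYS)}")
        _check_numeric("weights", w_over)
        wts = ControlWeights(**w_over)
    solver = dict(data.get("solver") or {})
    if set(solver) - _SOLVER_KEYS:
        raise ValueError(f"unknown solver keys: {sorted(set(solver) - _SOLVER_KEYS)}")
    return ExperimentConfig(
        experiment=exp,
        params=ModelParams(**p_over),
        thresholds=Thresholds(**th_over),
        schedule=sched,
        weights=wts,
        solver=solver,
        output_dir=data.get("output_dir", "results"),
        seed=data.get("seed"),
        T_init=float(data.get("T_init", 0.1)),
        strategy=data.get("strategy"),
        scheme=data.get("scheme", "SSSDDD"),
        raw=data,
    )


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return _build(data)


def config_from_dict(data: dict) -> ExperimentConfig:
    return _build(dict(data))


def _write_csv(df: pd.DataFrame, path: Path, cfg: ExperimentConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {cfg.provenance}\n")
        df.to_csv(fh, index=False)


def _write_summary(summary: dict, path: Path, cfg: ExperimentConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    summary = {"provenance": cfg.provenance, **summary}
    path.write_text(json.dumps(summary, indent=2, default=float))


def run_experiment(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Dispatch a named experiment; writes CSV outputs and a JSON summary,
    returns the summary dict."""
    out = Path(out_dir or cfg.output_dir)
    p, th = cfg.params, cfg.thresholds
    name = cfg.experiment
    try:
        summary = _DISPATCH[name](cfg, out)
    except KeyError:
        raise ValueError(f"experiment {name!r} has no runner; valid: {EXPERIMENTS}")
    _write_summary(summary, out / f"{name}_summary.json", cfg)
    return summary


# -- individual runners ----------------------------------------------------

def _run_fig3(cfg, out):
    rows, counts = [], {}
    for S in (0.0, 0.4, 1.0):
        eqs = find_equilibria(cfg.params, S, 0.0, cfg.thresholds)
        counts[S] = len(eqs)
        for e in eqs:
            rows.append(dict(S=S, S1=e.S1, S3=e.S3, B=e.B, X=e.X,
                             stable=e.stable, phase=e.phase))
    _write_csv(pd.DataFrame(rows), out / "fig3_equilibria.csv", cfg)
    return {"equilibrium_counts": {str(k): v for k, v in counts.items()}}


def _scan(cfg, J):
    step = float(cfg.solver.get("scan_step", 0.005))
    grid = np.arange(step, 1.0 + step / 2, step)
    return scan_S(cfg.params, grid, J, cfg.thresholds)


def _run_fig4(cfg, out):
    d = _scan(cfg, 0.0)
    _write_csv(d.to_frame(), out / "fig4_diagram.csv", cfg)
    w = bistability_window(d)
    return {"bistability_window": list(w) if w else None}


def _run_fig5(cfg, out):
    d = _scan(cfg, 1.0)
    df = d.to_frame()
    _write_csv(df, out / "fig5_diagram.csv", cfg)
    th = cfg.thresholds
    uni = {
        "S1_below_S1th": bool((df.S1 < th.S1_th).all()),
        "S3_above_S3th": bool((df.S3 > th.S3_th).all()),
        "B_above_Bth": bool((df.B > th.B_th).all()),
        "X_below_Xth": bool((df.X < th.X_th).all()),
        "single_branch": bool((d.counts() == 1).all()),
    }
    return {"uniformity": uni}


def _run_fig6(cfg, out):
    p, th = cfg.params, cfg.thresholds
    ic = default_initial_state(p, cfg.T_init)
    dr = dose_response(p, th, ic=ic)
    _write_csv(dr, out / "fig6_dose_response.csv", cfg)
    u15 = PulseControl((1.0, 3.0, 5.0, 7.0, 9.0), 2.0, 15.0)
    traj = simulate(p, th, ic, (0.0, 25.0), u15, method="rk4")
    ctrl = simulate(p, th, ic, (0.0, 25.0), method="rk4")
    _write_csv(traj.to_frame(), out / "fig6_treated.csv", cfg)
    _write_csv(ctrl.to_frame(), out / "fig6_control.csv", cfg)
    return {
        "T25_treated": float(traj["T"][-1]),
        "T25_control": float(ctrl["T"][-1]),
        "dose_response_T25": dict(zip(dr.u_S.astype(str), dr.T_eval)),
    }


def _base_schedule(cfg):
    return cfg.schedule or PulseSchedule(sequence="SSSDDD")


def _run_fig7(cfg, out):
    p, th = cfg.params, cfg.thresholds
    ic = default_initial_state(p, cfg.T_init)
    res = schedule_scan(p, th, _base_schedule(cfg), ic=ic)
    _write_csv(res, out / "fig7_schedules.csv", cfg)
    g1 = grouped_schedule_summary(res, "first-drug")
    g2 = grouped_schedule_summary(res, "first-half-weighting")
    _write_csv(g1.reset_index(), out / "fig7_group_first_drug.csv", cfg)
    _write_csv(g2.reset_index(), out / "fig7_group_first_half.csv", cfg)
    best = res.loc[res.normalized_volume.idxmin()]
    worst = res.loc[res.normalized_volume.idxmax()]
    return {
        "best_sequence": best.sequence,
        "best_normalized_volume": float(best.normalized_volume),
        "worst_sequence": worst.sequence,
        "worst_normalized_volume": float(worst.normalized_volume),
    }


def _run_fig8(cfg, out, sequences=None):
    p, th = cfg.params, cfg.thresholds
    base = _base_schedule(cfg)
    ic = default_initial_state(p, cfg.T_init)
    from .dosing import enumerate_schedules

    seqs = sequences or enumerate_schedules(base.N_S, base.N_D)
    rows = []
    for seq in seqs:
        sched = base.replace(sequence=seq)
        try:
            rate, total = min_rate_for_reduction(p, th, sched, ic=ic)
        except ValueError:
            rate, total = np.nan, np.nan
        rest, ok = max_resting_time(p, th, sched, ic=ic)
        rows.append(dict(sequence=seq, min_u_S=rate, total_dose=total,
                         max_rest=rest, rest_achieved=ok))
    df = pd.DataFrame(rows)
    _write_csv(df, out / "fig8_min_dose.csv", cfg)
    by = df.set_index("sequence")
    summary = {}
    for seq in ("SSSDDD", "DSDDSS"):
        if seq in by.index:
            summary[seq] = dict(
                min_u_S=float(by.loc[seq, "min_u_S"]),
                total_dose=float(by.loc[seq, "total_dose"]),
                max_rest=float(by.loc[seq, "max_rest"]),
            )
    return summary


def _run_fig9(cfg, out):
    p, th = cfg.params, cfg.thresholds
    base = _base_schedule(cfg)
    ic = default_initial_state(p, cfg.T_init)
    total_S, total_D = 123.0, 690.0
    frames = []
    for h_s in (2.0, 1.0, 0.5, 0.1):
        sched = rescale_rate_for_fixed_total(base.replace(h_s=h_s), total_S, "S")
        sched = rescale_rate_for_fixed_total(sched, total_D, "D")
        res = schedule_scan(p, th, sched, ic=ic)
        frames.append(res)
    df = pd.concat(frames, ignore_index=True)
    _write_csv(df, out / "fig9_duration.csv", cfg)
    means = df.groupby("h_s").normalized_volume.mean()
    return {"mean_normalized_volume_by_h_s": {str(k): float(v) for k, v in means.items()}}


def _run_fig10(cfg, out):
    runs = run_strategy_I(cfg.params, cfg.thresholds,
                          cfg.weights or STRATEGY_I_WEIGHTS,
                          ic=default_initial_state(cfg.params, cfg.T_init),
                          n_steps=int(cfg.solver.get("n_steps", 3000)))
    sol = runs["optimal"]["solution"]
    _write_csv(sol.to_frame(), out / "fig10_optimal.csv", cfg)
    _write_csv(sol.iterations, out / "fig10_iterations.csv", cfg)
    return {
        "final_T": {k: float(runs[k]["final_T"]) for k in ("alternating", "constant", "optimal")},
        "objective": {k: float(runs[k]["objective"]) for k in ("alternating", "constant", "optimal")},
        "totals_S": {k: float(runs[k]["total_S"]) for k in ("alternating", "constant", "optimal")},
        "totals_D": {k: float(runs[k]["total_D"]) for k in ("alternating", "constant", "optimal")},
        "totals_match": runs["totals_match"],
    }


def _run_fig11(cfg, out):
    df = half_life_experiment(cfg.params,
                              thresholds=cfg.thresholds,
                              n_steps=int(cfg.solver.get("n_steps", 3000)))
    _write_csv(df, out / "fig11_half_life.csv", cfg)
    piv = df.pivot(index="muS", columns="strategy", values="final_T")
    return {"final_T": {str(i): {k: float(v) for k, v in row.items()}
                        for i, row in piv.iterrows()}}


def _run_fig12(cfg, out):
    summaries = {}
    for scheme in ("SSSDDD", "DSDDSS"):
        res = run_strategy_II(cfg.params, scheme,
                              cfg.weights or STRATEGY_II_WEIGHTS,
                              thresholds=cfg.thresholds,
                              ic=default_initial_state(cfg.params, cfg.T_init),
                              n_steps=int(cfg.solver.get("n_steps", 3000)))
        _write_csv(res["solution"].to_frame(), out / f"fig12_{scheme}.csv", cfg)
        summaries[scheme] = dict(
            accumulated_IFN=float(res["accumulated_S"]),
            reduction_pct=float(res["reduction_pct"]),
        )
    return summaries


def _run_custom(cfg, out):
    p, th = cfg.params, cfg.thresholds
    sched = _base_schedule(cfg)
    ic = default_initial_state(p, cfg.T_init)
    from .dosing import simulate_schedule

    traj, nv = simulate_schedule(p, th, ic, sched)
    _write_csv(traj.to_frame(), out / "custom_trajectory.csv", cfg)
    return {"normalized_volume": float(nv), "final_T": float(traj["T"][-1])}


_DISPATCH = {
    "fig3": _run_fig3,
    "fig4": _run_fig4,
    "fig5": _run_fig5,
    "fig6": _run_fig6,
    "fig7": _run_fig7,
    "fig8": _run_fig8,
    "fig9": _run_fig9,
    "fig10": _run_fig10,
    "fig11": _run_fig11,
    "fig12": _run_fig12,
    "custom": _run_custom,
}
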