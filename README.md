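# statswitch

A simulator and analysis toolkit for the JAK/STAT–Bcl-2–BAX apoptosis
switch in tumour cells, coupled to logistic tumour growth and two drugs:
IFN-β (raises STAT1, suppresses STAT3) and cisplatin/DDP (degrades JAK2).
It is aimed at systems biologists and mathematical oncologists who want to
study how the *order and timing* of a two-drug infusion schedule decides
whether tumour cells commit to apoptosis — and to optimize that schedule
by Pontryagin optimal control.

## The model

Eight dimensionless ODEs for STAT1 (S₁), STAT3 (S₃), Bcl-2 (B), BAX (X),
tumour volume (T), IFN-β (S), JAK2 (J) and DDP (D). The signalling core is
a mutual-antagonism toggle with Hill-type autocatalysis,

    dS₁/dt = λ_S1 S + k₁k₂²/(k₂² + α S₃²) − S₁
    dS₃/dt = (λ_k + λ_J J)/(K + λ_S2 S) + k₃k₄²/(k₄² + β S₁²) − μ₃ S₃

with Bcl-2 slaved to the STATs and BAX slaved to Bcl-2. Cell killing is a
binary switch: tumour cells die (rate μ_T, plus a STAT1-dependent growth
brake) exactly while B < B_th and X > X_th,

    dT/dt = r (1 − k₉ S₁²/(k₁₀² + S₁²) · I) T (1 − T/T₀) − μ_T T · I,
    I = 𝟙{B < B_th, X > X_th}.

Drugs follow first-order pharmacokinetics driven by infusion rates u_S(t),
u_D(t). For a window of IFN-β levels (S ∈ [0.26, 0.57] at the default
calibration) the switch is bistable — two saddle-node folds bound a
hysteresis loop — and JAK2 moves the apoptosis onset: with J at baseline,
killing requires IFN-β levels just above S = 1, which is why infusion
*order* (DDP first lowers JAK2) changes the IFN-β dose needed.

The package provides:

- `model` — right-hand sides, apoptosis indicator/phase logic, event-aware
  and fixed-step simulation, dimensional conversion;
- `bifurcation` — equilibria with analytic-Jacobian stability, S-scans,
  the bistability window, hysteresis ramps, source-coefficient calibration;
- `dosing` — pulse schedules over {S, D} slots, schedule enumeration and
  scans, dose–response, minimum-dose and maximum-resting-time searches;
- `optimal_control` — the quadratic-cost objective, analytic adjoint
  system, and a monotone forward–backward sweep (projected-gradient update
  with line search; classic relaxed update available) for free-horizon
  (Strategy I) and slot-restricted (Strategy II) infusion optimization;
- `experiments` / `cli` — validated YAML/JSON configs and one-command
  reproduction of each packaged experiment.

## Worked example

```python
import numpy as np
import statswitch as sw

params = sw.ModelParams()
thresholds = sw.Thresholds()

# 1. bistable window of the intracellular switch (no JAK2)
diagram = sw.scan_S(params, np.arange(0.01, 1.0001, 0.01), J=0.0)
S_m, S_M = sw.bistability_window(diagram)
print(f"bistable IFN-beta window at J=0: [{S_m:.3f}, {S_M:.3f}]")

# 2. simulate the best slot schedule at the standard rates
ic = sw.default_initial_state(params)
sched = sw.PulseSchedule(sequence="SSSDDD", u_S_rate=8.2, u_D_rate=46.0)
traj, nv = sw.simulate_schedule(params, thresholds, ic, sched)
print(f"SSSDDD at u_S=8.2, u_D=46: final volume {traj['T'][-1]:.3f}, "
      f"normalized {nv:.3f}")

# 3. minimum IFN-beta rate for a 50% reduction
rate, total = sw.min_rate_for_reduction(params, thresholds, sched)
print(f"minimum u_S for 50% reduction: {rate:.2f} (total dose {total:.1f})")
```

prints

```
bistable IFN-beta window at J=0: [0.256, 0.574]
SSSDDD at u_S=8.2, u_D=46: final volume 0.800, normalized 0.226
minimum u_S for 50% reduction: 6.01 (total dose 90.1)
```

Reading: below S ≈ 0.26 only the survival state exists and above S ≈ 0.57
only the apoptotic one, with hysteresis in between. Three 5-unit IFN-β
slots followed by three DDP slots cut the day-30 tumour volume to 23% of
the no-IFN-β control at rate 8.2; bisection finds that rate 6.01 (90.1
total drug) is the cheapest schedule of this shape that still halves the
tumour.

The same analyses are available from the shell:

```sh
statswitch bifurcate --J 0 --step 0.005 --out diagram.csv
statswitch min-dose --sequence SSSDDD
statswitch optimize --strategy II --scheme SSSDDD --out solution.csv
statswitch reproduce fig4 --out results/
```

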