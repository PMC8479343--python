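"""Parameter sets, thresholds and reference scales of the signalling model.

All rate constants are dimensionless; time is measured in units of the
STAT1 half-life (the STAT1 decay rate is scaled to 1, and STAT1 and STAT3
share the same half-life, so the STAT3 decay coefficient ``mu3`` equals 1
by construction but is carried explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, replace

import numpy as np

__all__ = [
    "ModelParams",
    "Thresholds",
    "ReferenceScales",
    "SystemState",
    "STATE_VARS",
]

#: order of the state variables everywhere in the package
STATE_VARS = ("S1", "S3", "B", "X", "T", "S", "J", "D")

# Source coefficients coupling IFN-beta to the two STAT arms.  They are the
# only rate constants of the intracellular module without a published
# dimensionless value; the defaults below are fixed by a minimax fit to three
# structural anchors of the bifurcation analysis (the two saddle-node points
# of the J=0 scan at S=0.3 and S=0.53, and the persistence of the
# anti-apoptotic branch at J=1 up to S=1).  See docs/methods.md.
_LAMBDA_S1_DEFAULT = 0.8660
_LAMBDA_S2_DEFAULT = 5.0889

# fields that may be zero (all others must be strictly positive)
_NONNEG_FIELDS = {"lambda_S2", "gammaD", "k9"}


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless rate and shape constants of the eight-variable model.

    Defaults are the published parameter table of the model; ``lambda_S1``
    and ``lambda_S2`` carry the calibrated values described in the module
    docstring.
    """

    # STAT1 module: IFN-beta source, autocatalysis with STAT3 inhibition
    lambda_S1: float = _LAMBDA_S1_DEFAULT
    k1: float = 4.0
    k2: float = 1.0
    alpha: float = 1.5
    # STAT3 module: basal + JAK2 source suppressed by IFN-beta,
    # autocatalysis with STAT1 inhibition
    lambda_k: float = 1.0
    lambda_J: float = 4.0
    K: float = 5.0
    lambda_S2: float = _LAMBDA_S2_DEFAULT
    k3: float = 4.0
    k4: float = 1.0
    beta: float = 1.0
    mu3: float = 1.0
    # Bcl-2 module
    lambda1: float = 0.2
    k5: float = 1.0
    k6: float = 1.0
    gamma: float = 1.0
    lambda3: float = 1.2
    muB: float = 1.2
    # BAX module
    lambda2: float = 0.2
    k7: float = 4.0
    k8: float = 1.0
    delta: float = 1.0
    muX: float = 5.0
    # tumour module (logistic growth, STAT1-gated, apoptotic kill)
    r: float = 0.12
    k9: float = 1.0
    k10: float = 10.0
    T0: float = 100.0
    muT: float = 0.1
    # therapeutics: IFN-beta decay, JAK2 turnover, DDP action and decay
    muS: float = 4.8
    Js: float = 1.3
    gammaD: float = 1.0
    muJ: float = 1.3
    muD: float = 10.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v!r}")
            if f.name in _NONNEG_FIELDS:
                if v < 0:
                    raise ValueError(f"parameter {f.name!r} must be >= 0, got {v!r}")
            elif v <= 0:
                raise ValueError(f"parameter {f.name!r} must be > 0, got {v!r}")
        if self.k9 > 1.0:
            # k9 <= 1 keeps the STAT1-gated growth factor non-negative
            raise ValueError(f"k9 must be <= 1, got {self.k9!r}")

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Thresholds:
    """Phase-classification thresholds.

    ``B_th``/``X_th`` gate the apoptosis indicator of the tumour equation;
    ``S1_th``/``S3_th`` are descriptive only (used when reporting the
    signalling state, never in the dynamics).
    """

    S1_th: float = 1.8
    S3_th: float = 1.3
    B_th: float = 1.44
    X_th: float = 0.3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"threshold {f.name!r} must be finite and > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ReferenceScales:
    """Reference concentrations/volumes used for dimensional conversion.

    A dimensional quantity q maps to the dimensionless model via q / q_ref;
    dimensional time maps as t_dimless = mu_S1_dim * t_dim, with
    ``mu_S1_dim`` the dimensional STAT1 decay rate (per unit of
    dimensional time) serving as the time scale.
    """

    S1_ref: float = 2.43  # ug/ml
    S3_ref: float = 1.38  # ug/ml
    B_ref: float = 10.0  # nM
    X_ref: float = 351.0  # uM
    S_ref: float = 10.0  # ng/ml
    J_ref: float = 2.8  # nM
    D_ref: float = 10.0  # ug/ml
    T_ref: float = 100.0  # mm^3
    mu_S1_dim: float = 1.0  # 1/time; identity time scale unless overridden

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"reference scale {f.name!r} must be > 0")

    def as_state_vector(self) -> np.ndarray:
        """Scales ordered as STATE_VARS."""
        return np.array(
            [
                self.S1_ref,
                self.S3_ref,
                self.B_ref,
                self.X_ref,
                self.T_ref,
                self.S_ref,
                self.J_ref,
                self.D_ref,
            ]
        )


@dataclass(frozen=True)
class SystemState:
    """Values of the eight state variables at a single time point."""

    S1: float
    S3: float
    B: float
    X: float
    T: float
    S: float
    J: float
    D: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("state must be finite")
        if np.any(arr < 0):
            raise ValueError("state variables must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.S1, self.S3, self.B, self.X, self.T, self.S, self.J, self.D],
            dtype=float,
        )

    @classmethod
    def from_array(cls, y) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (8,):
            raise ValueError(f"expected 8 state values, got shape {y.shape}")
        return cls(*y)
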