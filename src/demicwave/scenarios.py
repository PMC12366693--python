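"""Priors, the six admixture scenarios and the cohabitation-time calibration.

Six scenario variants (AM1-AM6) describe how the HG->FA admixture rate gamma
varies over space and time during the farmer expansion:

========  =================  =========================================
scenario  spatial mode       temporal mode
========  =================  =========================================
AM1       constant           constant
AM2       increasing (10-zone gradient away from the FA origin)  constant
AM3       constant           ramp over the whole cohabitation period
AM4       increasing         ramp over the whole cohabitation period
AM5       decreasing         constant
AM6       two-zone (gamma_S / gamma_N split at latitude 43.2)  ramp over a
          variable number of generations t_inc within the cohabitation period
========  =================  =========================================

Ramp scenarios need to know how long HGs and FAs will cohabit, which depends
on (K_HG, K_FA, alpha_N).  As in the source method, a preliminary campaign
under AM1 is summarized by a generalized additive model (GAM) regressing the
mean cohabitation time on those three parameters; each ramp draw then sets
gamma_inc = 1 / t_inc with t_inc the predicted cohabitation time (AM3/AM4) or
a uniform integer in [1, predicted time] (AM6).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .world import WorldGrid


class PriorError(ValueError):
    pass


#: free parameters drawn uniformly, with the study's prior bounds
DEFAULT_PRIOR_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma": (0.0, 0.1),
    "gamma_S": (0.0, 0.1),
    "gamma_N": (0.0, 0.1),
    "K_HG": (270, 450),
    "K_FA": (1200, 2400),
    "P_LDD": (0.0, 0.025),
    "alpha_N": (0.15, 0.37),
    "m_FA": (0.1, 0.5),
    "eps": (4.5e-5, 1.2e-4),
}

#: parameters held fixed across simulations
DEFAULT_FIXED: dict[str, float] = {
    "m_HG": 0.15,
    "r_HG": 0.2,
    "r_FA": 0.55,
    "ldd_shape": 1.209,
    "ldd_rate": 0.15046,
    "alpha_S": 1.0,
}


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds plus fixed parameter values."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS)
    )
    fixed: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo <= hi:
                raise PriorError(f"empty prior range for {name}: ({lo}, {hi})")

    def with_bounds(self, **overrides: tuple[float, float]) -> "PriorSpec":
        b = dict(self.bounds)
        b.update(overrides)
        return replace(self, bounds=b)


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    spatial_mode: str  # constant | increasing | decreasing | two-zone
    temporal_mode: str  # constant | full-ramp | variable-ramp


SCENARIOS: dict[str, ScenarioSpec] = {
    "AM1": ScenarioSpec("AM1", "constant", "constant"),
    "AM2": ScenarioSpec("AM2", "increasing", "constant"),
    "AM3": ScenarioSpec("AM3", "constant", "full-ramp"),
    "AM4": ScenarioSpec("AM4", "increasing", "full-ramp"),
    "AM5": ScenarioSpec("AM5", "decreasing", "constant"),
    "AM6": ScenarioSpec("AM6", "two-zone", "variable-ramp"),
}

#: free parameters actually used by each scenario
_SCENARIO_PARAMS = {
    "AM1": ("gamma",),
    "AM2": ("gamma",),
    "AM3": ("gamma",),
    "AM4": ("gamma",),
    "AM5": ("gamma",),
    "AM6": ("gamma_S", "gamma_N"),
}


@dataclass(frozen=True)
class ParameterDraw:
    """One simulation's parameter vector (plus derived ramp settings)."""

    scenario_id: str
    gamma: float = 0.0
    gamma_S: float = 0.0
    gamma_N: float = 0.0
    t_inc: int = 1
    gamma_inc: float = 0.0
    K_HG: int = 360
    K_FA: int = 1800
    m_FA: float = 0.3
    P_LDD: float = 0.0
    alpha_N: float = 0.25
    eps: float = 7e-5

    def free_values(self) -> dict[str, float]:
        names = list(_SCENARIO_PARAMS[self.scenario_id]) + [
            "K_HG", "K_FA", "m_FA", "P_LDD", "alpha_N", "eps",
        ]
        if SCENARIOS[self.scenario_id].temporal_mode == "variable-ramp":
            names.append("t_inc")
        return {n: getattr(self, n) for n in names}


class CohabCalibration:
    """Smooth additive fit of mean cohabitation time on (K_HG, K_FA, alpha_N).

    Wraps a Gaussian GAM with one B-spline smooth per covariate; predictions
    are clipped below at 1 generation.
    """

    COVARIATES = ("K_HG", "K_FA", "alpha_N")

    def __init__(self, model_result=None, smoother=None, meta: Optional[dict] = None):
        self._result = model_result
        self._smoother = smoother
        self.meta = meta or {}

    def predict(self, k_hg, k_fa, alpha_n) -> np.ndarray:
        raise NotImplementedError

    def predict_one(self, k_hg: float, k_fa: float, alpha_n: float) -> float:
        return float(self.predict([k_hg], [k_fa], [alpha_n])[0])


class ConstantCalibration(CohabCalibration):
    """Degenerate calibration predicting a fixed cohabitation time."""

    def __init__(self, value: float):
        self.value = max(1.0, float(value))
        self.meta = {"constant": self.value}

    def predict(self, k_hg, k_fa, alpha_n) -> np.ndarray:
        n = len(np.atleast_1d(np.asarray(k_hg)))
        return np.full(n, self.value)


def calibrate_cohabitation(
    k_hg: np.ndarray,
    k_fa: np.ndarray,
    alpha_n: np.ndarray,
    cohab: np.ndarray,
    df: int = 5,
) -> CohabCalibration:
    """Fit the GAM mapping (K_HG, K_FA, alpha_N) -> mean cohabitation time."""
    from statsmodels.gam.api import BSplines, GLMGam

    k_hg = np.asarray(k_hg, dtype=float)
    k_fa = np.asarray(k_fa, dtype=float)
    alpha_n = np.asarray(alpha_n, dtype=float)
    cohab = np.asarray(cohab, dtype=float)
    if len(cohab) < 100:
        raise PriorError("need at least 100 training rows for calibration")
    X = np.column_stack([k_hg, k_fa, alpha_n])
    if np.any(np.ptp(X, axis=0) == 0):
        raise PriorError("degenerate calibration design: constant covariate")
    if np.ptp(cohab) == 0:
        return ConstantCalibration(cohab[0])
    smoother = BSplines(X, df=[df] * 3, degree=[3] * 3, include_intercept=False)
    model = GLMGam(cohab, exog=np.ones((len(cohab), 1)), smoother=smoother)
    result = model.fit()

    class _Fitted(CohabCalibration):
        def predict(self, k_hg, k_fa, alpha_n):
            Xn = np.column_stack(
                [
                    np.clip(np.atleast_1d(np.asarray(k_hg, float)), X[:, 0].min(), X[:, 0].max()),
                    np.clip(np.atleast_1d(np.asarray(k_fa, float)), X[:, 1].min(), X[:, 1].max()),
                    np.clip(np.atleast_1d(np.asarray(alpha_n, float)), X[:, 2].min(), X[:, 2].max()),
                ]
            )
            pred = result.predict(np.ones((len(Xn), 1)), exog_smooth=Xn)
            return np.maximum(1.0, np.asarray(pred, dtype=float))

    calib = _Fitted(result, smoother, meta={"n_train": len(cohab), "df": df})
    return calib


def draw_parameters(
    priors: PriorSpec,
    scenario: ScenarioSpec | str,
    rng: np.random.Generator,
    calibration: Optional[CohabCalibration] = None,
) -> ParameterDraw:
    """Draw one parameter vector uniformly within the prior bounds.

    Ramp scenarios require a cohabitation calibration: AM3/AM4 set
    t_inc to the predicted mean cohabitation time (gamma reaches its maximum
    exactly at the predicted cohabitation end); AM6 draws t_inc uniformly in
    [1, predicted time] and gamma rises over t_inc generations then holds.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    b = priors.bounds

    def u(name: str) -> float:
        lo, hi = b[name]
        return float(rng.uniform(lo, hi))

    kw: dict = {
        "scenario_id": scenario.id,
        "K_HG": int(round(u("K_HG"))),
        "K_FA": int(round(u("K_FA"))),
        "m_FA": u("m_FA"),
        "P_LDD": u("P_LDD"),
        "alpha_N": u("alpha_N"),
        "eps": u("eps"),
    }
    if scenario.id == "AM6":
        kw["gamma_S"] = u("gamma_S")
        kw["gamma_N"] = u("gamma_N")
    else:
        kw["gamma"] = u("gamma")

    if scenario.temporal_mode != "constant":
        if calibration is None:
            raise PriorError(f"{scenario.id} requires a cohabitation calibration")
        cohab = calibration.predict_one(kw["K_HG"], kw["K_FA"], kw["alpha_N"])
        cohab_int = max(1, int(round(cohab)))
        if scenario.temporal_mode == "full-ramp":
            t_inc = cohab_int
        else:  # variable-ramp (AM6)
            t_inc = int(rng.integers(1, cohab_int + 1))
        kw["t_inc"] = t_inc
        kw["gamma_inc"] = 1.0 / t_inc
    return ParameterDraw(**kw)


def spatial_gamma_profile(
    scenario: ScenarioSpec | str,
    world: WorldGrid,
    fa_origin: int,
    gamma_max: float = 0.0,
    gamma_S: float = 0.0,
    gamma_N: float = 0.0,
    n_zones: int = 10,
) -> np.ndarray:
    """Per-deme maximum admixture rate for a scenario.

    'constant': gamma_max everywhere.  'increasing'/'decreasing': ``n_zones``
    equal-width grid-distance bands from the FA origin; band k (k = 1..10,
    outward) carries k/10 * gamma_max ('increasing') or the reversed sequence
    ('decreasing', gamma_max near the origin down to gamma_max/10 at the far
    end).  'two-zone': gamma_S in cells at or below latitude 43.2, gamma_N
    above it.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    C = world.n_cells
    if scenario.spatial_mode == "constant":
        return np.full(C, gamma_max)
    if scenario.spatial_mode == "two-zone":
        return np.where(world.north_mask_flat(), gamma_N, gamma_S)
    # distance bands from the FA origin (grid Euclidean distance, deme widths)
    r0, c0 = world.rowcol_of(fa_origin)
    rows, cols = np.divmod(np.arange(C), world.n_cols)
    dist = np.hypot(rows - r0, cols - c0)
    dmax = dist[world.land_flat].max() if world.land_flat.any() else dist.max()
    band = np.minimum(
        n_zones, np.floor(dist / max(dmax, 1e-9) * n_zones).astype(int) + 1
    )
    frac = band / n_zones
    if scenario.spatial_mode == "decreasing":
        frac = (n_zones + 1 - band) / n_zones
    return gamma_max * frac
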