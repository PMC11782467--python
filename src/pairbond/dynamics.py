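"""Integration to equilibrium, strategy classification and sex ratios.

The central question for each parameter set is which male strategy's
lineage survives at the long-run equilibrium.  The system is integrated
until the relative rate of change of every compartment stays below a
tolerance over a sustained window, then the final state is classified:
a strategy is extinct when its male compartments hold less than a small
fraction of the total population.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._integrate import solve_dense, solve_equilibrium
from .model import (
    COMPARTMENTS,
    NEGATIVITY_TOLERANCE,
    PopulationState,
    _coeffs,
    _rhs_raw,
)
from .params import ParameterSet, derive_rates

__all__ = [
    "IntegrationSettings",
    "Dominance",
    "SexRatios",
    "EquilibriumResult",
    "Trajectory",
    "integrate",
    "find_equilibrium",
    "classify_dominance",
    "sex_ratios",
]

_IX = {name: i for i, name in enumerate(COMPARTMENTS)}
_GUARD_MALES = [_IX[n] for n in ("G", "PGg", "PG", "PMm", "PMg", "PM")]

# Table-2 ratio index sets
_OSR_NUM = [_IX[n] for n in ("M", "G")]
_OSR_DEN = [_IX[n] for n in ("FM", "FG")]
_ASR_NUM = [_IX[n] for n in ("M", "G", "PGg", "PG", "PMm", "PMg", "PM")]
_ASR_DEN = [_IX[n] for n in ("FM", "FG", "FGm", "FMm", "FGg", "FMg",
                             "PGg", "PMg", "PG", "PMm", "PM")]


@dataclass(frozen=True)
class IntegrationSettings:
    """Numerical controls for equilibrium runs.

    ``convergence_tol`` bounds max_i |dS_i/dt| / (|S_i| + 1e-12), which
    must hold throughout a ``window`` of 50 years before the run is
    declared converged.  ``extinction_threshold`` is the fraction of the
    total population below which a lineage counts as extinct.

    The horizon default is large because strategy sorting is slow: the
    losing lineage typically decays at only ~1e-4 per year near the
    reference parameters, so meeting the residual criterion takes on the
    order of 1e5 simulated years.  Step tolerances are tight so that the
    integration-noise floor of the residual (roughly rtol times the
    fastest system rate) sits well below ``convergence_tol``; loosening
    rtol much past 1e-9 makes the convergence check flicker.  ``method``
    selects the compiled
    adaptive Dormand-Prince stepper (``"rk45"``, default) or any scipy
    ``solve_ivp`` method name (e.g. ``"LSODA"``).
    """

    t_max: float = 5e5
    convergence_tol: float = 1e-8
    extinction_threshold: float = 1e-6
    rtol: float = 1e-10
    atol: float = 1e-20
    window: float = 50.0
    method: str = "rk45"

    def __post_init__(self) -> None:
        for name in ("t_max", "convergence_tol", "extinction_threshold",
                     "rtol", "atol", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.extinction_threshold >= 0.5:
            raise ValueError("extinction_threshold must be below 0.5")


class Dominance(str, Enum):
    """Outcome of the strategy competition at equilibrium."""

    MULTIPLE_MATING = "multiple_mating"
    GUARDING = "guarding"
    COEXISTENCE = "coexistence"
    EXTINCT = "extinct"


@dataclass(frozen=True)
class SexRatios:
    """Adult and operational sex ratios at a state.

    OSR counts only adults currently able to conceive: unpaired fertile
    males over free fertile females.  ASR counts all fertile-age adults,
    paired or not.  A zero denominator leaves the ratio undefined
    (value NaN, flag False).
    """

    asr: float
    osr: float
    asr_defined: bool = True
    osr_defined: bool = True


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed solution of the system."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 17)
    params: ParameterSet

    def state_at(self, i: int) -> PopulationState:
        return PopulationState(self.states[i])

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: t, the 17 compartments, asr and osr."""
        df = pd.DataFrame(self.states, columns=list(COMPARTMENTS))
        df.insert(0, "t", self.t)
        ratios = [sex_ratios(PopulationState(row)) for row in self.states]
        df["asr"] = [r.asr for r in ratios]
        df["osr"] = [r.osr for r in ratios]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False,
                                   float_format="%.12g")


@dataclass(frozen=True)
class EquilibriumResult:
    """Terminal state of an equilibrium run plus its classification."""

    final_state: PopulationState
    t_final: float
    converged: bool
    residual: float
    dominance: Dominance
    ratios: SexRatios
    initial_total: float

    def to_dict(self) -> dict:
        return {
            "final_state": self.final_state.to_dict(),
            "t_final": self.t_final,
            "converged": self.converged,
            "residual": self.residual,
            "dominance": self.dominance.value,
            "ratios": {
                "asr": self.ratios.asr,
                "osr": self.ratios.osr,
                "asr_defined": self.ratios.asr_defined,
                "osr_defined": self.ratios.osr_defined,
            },
            "initial_total": self.initial_total,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class IntegrationError(RuntimeError):
    """Raised when the solver fails before reaching the horizon."""


def _clamp(y: np.ndarray, t: float) -> np.ndarray:
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state at t={t:.3f}")
    if np.any(y < -NEGATIVITY_TOLERANCE):
        i = int(np.argmin(y))
        raise IntegrationError(
            f"compartment {COMPARTMENTS[i]} fell to {y.min():.3e} "
            f"at t={t:.3f}"
        )
    return np.maximum(y, 0.0)


def _residual(y: np.ndarray, dy: np.ndarray) -> float:
    return float(np.max(np.abs(dy) / (np.abs(y) + 1e-12)))


_FAIL_MESSAGES = {
    2: "a compartment fell below the negativity tolerance",
    3: "non-finite state encountered",
    4: "step size collapsed",
}


def integrate(
    params: ParameterSet,
    init: PopulationState | None = None,
    settings: IntegrationSettings | None = None,
    t_max: float | None = None,
    n_points: int = 400,
) -> Trajectory:
    """Solve the system over a fixed horizon and return the trajectory.

    Produces ``n_points`` evenly spaced output states (at least 200, so
    the result is dense enough to plot).  ``t_max`` defaults to the
    settings horizon, which is sized for equilibrium runs; pass an
    explicit horizon for plotting-scale trajectories.
    """
    settings = settings or IntegrationSettings()
    init = init or PopulationState.default_initial()
    horizon = t_max if t_max is not None else settings.t_max
    n_points = max(n_points, 200)
    c = np.array(_coeffs(params, derive_rates(params)))
    t_eval = np.linspace(0.0, horizon, n_points)
    if settings.method == "rk45":
        states, status, t_fail = solve_dense(
            init.values, c, t_eval, settings.rtol, settings.atol)
        if status != 0:
            raise IntegrationError(
                f"integration failed at t={t_fail:.3f}: "
                f"{_FAIL_MESSAGES[status]}"
            )
    else:
        sol = solve_ivp(
            lambda t, y: _rhs_raw(y, c), (0.0, horizon), init.values,
            method=settings.method, t_eval=t_eval,
            rtol=settings.rtol, atol=settings.atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed near t={sol.t[-1]:.3f}: {sol.message}"
            )
        states = sol.y.T
    states = np.stack([_clamp(y, t) for t, y in zip(t_eval, states)])
    return Trajectory(t=t_eval, states=states, params=params)


def find_equilibrium(
    params: ParameterSet,
    init: PopulationState | None = None,
    settings: IntegrationSettings | None = None,
) -> EquilibriumResult:
    """Integrate until the system settles and classify the outcome.

    The run stops once the relative derivative norm stays below
    ``convergence_tol`` throughout a sustained window of
    ``settings.window`` years, or at ``t_max`` (flagged unconverged).
    """
    settings = settings or IntegrationSettings()
    init = init or PopulationState.default_initial()
    c = np.array(_coeffs(params, derive_rates(params)))

    if settings.method == "rk45":
        y, t, residual, status = solve_equilibrium(
            init.values, c, settings.t_max, settings.rtol, settings.atol,
            settings.convergence_tol, settings.window,
        )
        if status in _FAIL_MESSAGES:
            raise IntegrationError(
                f"integration failed at t={t:.3f}: {_FAIL_MESSAGES[status]}"
            )
        converged = status == 0
        y = _clamp(y, t)
    else:
        fun = lambda t, y: _rhs_raw(y, c)  # noqa: E731
        y = init.values
        t = 0.0
        converged = False
        checkpoints = np.linspace(0.0, settings.window, 6)[1:]
        residual = _residual(y, _rhs_raw(y, c))
        while t < settings.t_max:
            t_end = min(t + settings.window, settings.t_max)
            sol = solve_ivp(
                fun, (t, t_end), y,
                method=settings.method,
                t_eval=t + checkpoints[checkpoints <= t_end - t + 1e-9],
                rtol=settings.rtol, atol=settings.atol,
            )
            if not sol.success:
                raise IntegrationError(
                    "integration failed near "
                    f"t={sol.t[-1] if len(sol.t) else t:.3f}: {sol.message}"
                )
            window_ok = True
            for ti, yi in zip(sol.t, sol.y.T):
                yi = _clamp(yi, ti)
                residual = _residual(yi, _rhs_raw(yi, c))
                if residual >= settings.convergence_tol:
                    window_ok = False
            y = _clamp(sol.y[:, -1], sol.t[-1])
            t = sol.t[-1]
            if window_ok:
                converged = True
                break

    final = PopulationState(y)
    return EquilibriumResult(
        final_state=final,
        t_final=t,
        converged=converged,
        residual=residual,
        dominance=classify_dominance(final, settings.extinction_threshold),
        ratios=sex_ratios(final),
        initial_total=init.total(),
    )


def classify_dominance(
    state: PopulationState,
    extinction_threshold: float = 1e-6,
) -> Dominance:
    """Which male lineage survives at a (near-)equilibrium state.

    The guarding lineage is counted from G plus every pair compartment
    (paired males all guard); the multiple-mating lineage from M.  A
    lineage is extinct when its total falls below
    ``extinction_threshold`` times the whole population.
    """
    vec = state.values
    total = float(vec.sum())
    if total <= 0.0:
        return Dominance.EXTINCT
    guard = float(vec[_GUARD_MALES].sum())
    mult = float(vec[_IX["M"]])
    cutoff = extinction_threshold * total
    guard_alive = guard >= cutoff
    mult_alive = mult >= cutoff
    if guard_alive and mult_alive:
        return Dominance.COEXISTENCE
    if guard_alive:
        return Dominance.GUARDING
    if mult_alive:
        return Dominance.MULTIPLE_MATING
    return Dominance.EXTINCT


def sex_ratios(state: PopulationState) -> SexRatios:
    """Adult and operational sex ratios of a state (Table-2 definitions)."""
    vec = state.values
    osr_den = float(vec[_OSR_DEN].sum())
    asr_den = float(vec[_ASR_DEN].sum())
    osr_defined = osr_den > 0.0
    asr_defined = asr_den > 0.0
    osr = float(vec[_OSR_NUM].sum()) / osr_den if osr_defined else math.nan
    asr = float(vec[_ASR_NUM].sum()) / asr_den if asr_defined else math.nan
    return SexRatios(asr=asr, osr=osr,
                     asr_defined=asr_defined, osr_defined=osr_defined)
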