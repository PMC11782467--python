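"""Compartments, rate laws, and the right-hand side of the ODE system.

The population is divided into 17 compartments: free fertile females by
inherited trait (FM, FG), unpaired males by strategy (M multiple-mating,
G guarding), unpaired caring females by own trait and dependant trait
(FMm, FGg, FGm, FMg — uppercase letter is the mother's trait, lowercase
the dependant's), pairs of a guarding male and a female (PGg, PG, PMm,
PMg, PM — pairs without a trailing lowercase letter are dependant-free),
post-fertile females (X, Xm, Xg) and retired males (Y).

Adult mortality is density dependent: the female death rate is the larger
of the baseline 1/L and a crowding term proportional to the number of
carers, which holds the population near its initial size.  Because that
crowding term uses absolute densities, results depend on the overall
scale of the state; the canonical initial condition (total density 2.0)
is the reference scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .params import DerivedRates, ParameterSet, derive_rates

__all__ = [
    "COMPARTMENTS",
    "NEGATIVITY_TOLERANCE",
    "PopulationState",
    "StateDerivative",
    "female_death_rate",
    "male_death_rate",
    "theft_probability",
    "rhs",
]

#: Canonical compartment order used for all state vectors.
COMPARTMENTS = (
    "FM", "FG", "M", "G",
    "FMm", "FGg", "FGm", "FMg",
    "PGg", "PG", "PMm", "PMg", "PM",
    "X", "Xm", "Xg", "Y",
)

_INDEX = {name: i for i, name in enumerate(COMPARTMENTS)}

#: Components more negative than this indicate integration failure;
#: anything in (-NEGATIVITY_TOLERANCE, 0) is treated as numerical noise.
NEGATIVITY_TOLERANCE = 1e-10

# carer compartments entering the density-dependent death rate and the
# birth flux (nine of them: all females currently caring for a dependant)
_CARER_NAMES = ("FMm", "FGg", "FGm", "FMg", "PGg", "PMm", "PMg", "Xg", "Xm")
_CARERS = tuple(_INDEX[n] for n in _CARER_NAMES)

_PAIR_NAMES = ("PGg", "PG", "PMm", "PMg", "PM")
_PAIRS = tuple(_INDEX[n] for n in _PAIR_NAMES)


class PopulationState:
    """Densities of the 17 population compartments at one time point.

    Thin wrapper over a float vector in :data:`COMPARTMENTS` order with
    attribute access by compartment name.
    """

    __slots__ = ("_values",)

    def __init__(self, values=None, **by_name: float):
        if values is not None and by_name:
            raise TypeError("pass either a vector or keyword densities")
        if values is None:
            unknown = set(by_name) - set(COMPARTMENTS)
            if unknown:
                raise ValueError(f"unknown compartments: {sorted(unknown)}")
            vec = np.zeros(len(COMPARTMENTS))
            for name, v in by_name.items():
                vec[_INDEX[name]] = v
        else:
            vec = np.asarray(values, dtype=float).copy()
            if vec.shape != (len(COMPARTMENTS),):
                raise ValueError(
                    f"state vector must have length {len(COMPARTMENTS)}"
                )
        self._values = _validate_and_clamp(vec)

    @classmethod
    def default_initial(cls) -> "PopulationState":
        """The canonical initial condition: FM = FG = M = G = 0.5, rest 0."""
        return cls(FM=0.5, FG=0.5, M=0.5, G=0.5)

    @property
    def values(self) -> np.ndarray:
        return self._values.copy()

    def __getattr__(self, name: str) -> float:
        try:
            return float(self._values[_INDEX[name]])
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return float(self._values[_INDEX[name]])

    def __iter__(self) -> Iterator[float]:
        return iter(self._values)

    def total(self) -> float:
        """Total density counting each pair as two adults."""
        return float(self._values.sum() + self._values[list(_PAIRS)].sum())

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(COMPARTMENTS, self._values)}

    def __repr__(self) -> str:
        nonzero = {n: round(v, 6) for n, v in self.to_dict().items() if v}
        return f"PopulationState({nonzero})"


@dataclass(frozen=True)
class StateDerivative:
    """Signed per-year rates of change, one per compartment."""

    values: np.ndarray

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[_INDEX[name]])
        except KeyError:
            raise AttributeError(name) from None

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(COMPARTMENTS, self.values)}


def _validate_and_clamp(vec: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(vec)):
        bad = COMPARTMENTS[int(np.argmax(~np.isfinite(vec)))]
        raise ValueError(f"non-finite density in compartment {bad}")
    if np.any(vec < -NEGATIVITY_TOLERANCE):
        bad = COMPARTMENTS[int(np.argmin(vec))]
        raise ValueError(
            f"compartment {bad} is negative beyond tolerance "
            f"({vec.min():.3e}); integration failure"
        )
    return np.maximum(vec, 0.0)


def _coeffs(params: ParameterSet, derived: DerivedRates) -> tuple:
    return (params.rho, params.beta, derived.delta_m, params.delta_g,
            params.chi, params.q_star, derived.omega_F, derived.omega_M,
            params.L, params.male_mortality_factor)


def _mu_F(y, beta: float, L: float) -> float:
    carer_sum = 0.0
    for i in _CARERS:
        carer_sum += y[i]
    return max(1.0 / L, 0.5 * beta * carer_sum)


def female_death_rate(state: PopulationState, params: ParameterSet) -> float:
    """Density-dependent female death rate, per year.

    max{1/L, (beta/2) * sum of the nine carer compartments}: the crowding
    term balances the birth flux so the population holds at its initial
    size unless that would push mortality below the baseline 1/L.
    """
    return _mu_F(state._values, params.beta, params.L)


def male_death_rate(state: PopulationState, params: ParameterSet) -> float:
    """Male death rate: the female rate scaled by the mortality factor."""
    return params.male_mortality_factor * female_death_rate(state, params)


def theft_probability(state: PopulationState, params: ParameterSet) -> float:
    """Probability q that a guarded paternity is stolen.

    q = q_star * M/(M+G): theft succeeds at rate q_star and requires a
    multiple-mating male, hence the proportionality to their share of the
    unpaired male pool.  Defined as 0 when no unpaired males remain.
    """
    MG = state.M + state.G
    if MG <= 0.0:
        return 0.0
    return params.q_star * state.M / MG


def _rhs_raw(y, c) -> np.ndarray:
    """Time derivative of the 17 compartments; y in COMPARTMENTS order."""
    (rho, beta, delta_m, delta_g, chi, q_star,
     omega_F, omega_M, L, male_factor) = c
    (FM, FG, M, G, FMm, FGg, FGm, FMg,
     PGg, PG, PMm, PMg, PM, X, Xm, Xg, Y) = y

    muF = max(1.0 / L,
              0.5 * beta * (FMm + FGg + FGm + FMg + PGg + PMm + PMg
                            + Xg + Xm))
    muM = male_factor * muF
    MG = M + G
    if MG > 0.0:
        fM = M / MG
        fG = G / MG
        rho_free = rho  # free females find a mate in the unpaired pool
    else:
        fM = fG = 0.0
        rho_free = 0.0  # no unpaired males: free-female matings vanish
    q = fM * q_star

    m_carers = FMm + FGm + PMm + Xm          # dependants with the m trait
    g_carers = FGg + FMg + PGg + PMg + Xg    # dependants with the g trait

    dFM = (-rho_free * FM + 0.5 * beta * m_carers
           + (beta + delta_m) * FMm + (beta + delta_g) * FMg
           + (chi + muM) * PM - (omega_F + muF) * FM)
    dFG = (-rho_free * FG + 0.5 * beta * g_carers
           + (beta + delta_g) * FGg + (beta + delta_m) * FGm
           + (chi + muM) * PG - (omega_F + muF) * FG)
    dM = (0.5 * beta * m_carers + 0.5 * q * beta * g_carers
          - (omega_M + muM) * M)
    dG = (-rho * fG * (FM + FG) + 0.5 * (1.0 - q) * beta * g_carers
          + (chi + omega_F + muF) * (PM + PG + PMg + PGg + PMm)
          - (omega_M + muM) * G)
    dFMm = (rho * fM * FM + (chi + muM) * PMm
            - (beta + delta_m + omega_F + muF) * FMm)
    dFGg = (0.5 * rho * fM * FG + (chi + muM) * PGg
            - (beta + delta_g + omega_F + muF) * FGg)
    dFGm = 0.5 * rho * fM * FG - (beta + delta_m + omega_F + muF) * FGm
    dFMg = (chi + muM) * PMg - (beta + delta_g + omega_F + muF) * FMg
    dPGg = (rho * fG * FG + rho * PG
            - (beta + delta_g + chi + omega_F + muM + muF) * PGg)
    dPG = (-rho * PG + (beta + delta_g) * PGg
           - (chi + omega_F + muM + muF) * PG)
    dPMm = (0.5 * rho * fG * FM + 0.5 * rho * PM
            - (beta + delta_m + chi + omega_F + muM + muF) * PMm)
    dPMg = (0.5 * rho * fG * FM + 0.5 * rho * PM
            - (beta + delta_g + chi + omega_F + muM + muF) * PMg)
    dPM = (-rho * PM + (beta + delta_m) * PMm + (beta + delta_g) * PMg
           - (chi + omega_F + muM + muF) * PM)
    dX = (omega_F * (FM + FG + PM + PG)
          + (beta + delta_m) * Xm + (beta + delta_g) * Xg - muF * X)
    dXm = omega_F * (FMm + FGm + PMm) - (beta + delta_m + muF) * Xm
    dXg = (omega_F * (FGg + FMg + PGg + PMg)
           - (beta + delta_g + muF) * Xg)
    dY = omega_M * (M + G) - muM * Y

    return np.array([dFM, dFG, dM, dG, dFMm, dFGg, dFGm, dFMg,
                     dPGg, dPG, dPMm, dPMg, dPM, dX, dXm, dXg, dY])


def rhs(
    state: PopulationState,
    params: ParameterSet,
    derived: DerivedRates | None = None,
) -> StateDerivative:
    """Evaluate the full system's time derivative at a state.

    Mortality, theft probability and the mating fractions M/(M+G),
    G/(M+G) are evaluated from the current state; all mating fluxes
    vanish when no unpaired males remain.
    """
    if derived is None:
        derived = derive_rates(params)
    return StateDerivative(_rhs_raw(state._values, _coeffs(params, derived)))
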