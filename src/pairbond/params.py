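"""Model parameters and the life-history rates derived from them.

The model tracks a population in which males compete for paternities with
one of two pure strategies — multiple mating (return to the mating pool
after every conception) or mate guarding (form an exclusive pair bond) —
and in which females may outlive their fertility.  All rates are per year;
population densities are dimensionless.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Any, Mapping

__all__ = [
    "FertilityCase",
    "ParameterSet",
    "DerivedRates",
    "derive_rates",
    "dependant_death_rate",
    "female_maturity_age",
    "HUMAN_LIFESPAN",
    "CHIMP_LIFESPAN",
]

#: Expected adult lifespans (years) for the two reference species.
HUMAN_LIFESPAN = 38.0
CHIMP_LIFESPAN = 22.0

#: Age (years) at which female fertility ends in the two-case fertility model.
FERTILITY_END_AGE = 45.0


class FertilityCase(str, Enum):
    """Whether female fertility ends before death.

    ``CASE1``: fertility never ends (omega_F = 0), so there is no
    post-fertile life stage.  ``CASE2``: fertility ends at age 45, giving
    long-lived populations a distinct post-fertile female stage.
    """

    CASE1 = "case1"
    CASE2 = "case2"


def dependant_death_rate(survival: float = 0.65, years: float = 4.0) -> float:
    """Exponential death rate implied by a survival fraction over a period.

    The default reproduces the baseline dependant death rate: 65% of
    dependants surviving to age four gives -(1/4)*ln(0.65) ~ 0.11 per year.
    """
    if not 0.0 < survival <= 1.0 or years <= 0:
        raise ValueError("survival must be in (0, 1] and years positive")
    return -math.log(survival) / years


def female_maturity_age(L: float) -> float:
    """Age of female sexual maturity under the L/2 life-history scaling."""
    return L / 2.0


@dataclass(frozen=True)
class ParameterSet:
    """All model constants.

    Parameters
    ----------
    rho
        Female productive-mating (conception) rate, per year.  The default
        of 3/yr corresponds to a 4-month mean conception time.
    delta_g
        Death rate of dependants sired by guarding males, per year.
    k
        Relative guarding-advantage multiplier; multiple-mating dependants
        die at ``delta_m = k * delta_g``.  The natural range is 1 <= k <= 2.
    beta
        Rate at which dependants reach independence, per year.  Its
        reciprocal is the interbirth interval.
    q_star
        Success rate of paternity theft by multiple-mating males, in [0, 1].
    chi
        Pair-bond break-up rate, per year.  ``chi = 0`` means bonds never
        break (mean duration 1/chi is infinite).
    L
        Expected adult lifespan in years.
    fertility_case
        Selects whether female fertility ends (see :class:`FertilityCase`).
    male_mortality_factor
        Multiplier applied to the female death rate for males (default
        1.09, a 9% higher minimum death rate).
    male_frailty_scale
        Males retire from mate competition at rate 1/(scale * L); the
        default scale 1.6 matches the ~60/38 and ~35/22 age ratios at
        which human and chimpanzee male fertility tails off.
    """

    rho: float = 3.0
    delta_g: float = 0.11
    k: float = 1.0
    beta: float = 0.25
    q_star: float = 0.0
    chi: float = 0.0
    L: float = HUMAN_LIFESPAN
    fertility_case: FertilityCase = FertilityCase.CASE2
    male_mortality_factor: float = 1.09
    male_frailty_scale: float = 1.6

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fertility_case", FertilityCase(self.fertility_case)
        )
        for name in ("rho", "delta_g", "beta", "chi", "q_star",
                     "male_mortality_factor", "male_frailty_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.q_star <= 1.0:
            raise ValueError("q_star must lie in [0, 1]")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.k < 1.0 or self.k > 2.0:
            warnings.warn(
                f"k={self.k} is outside the natural range [1, 2]",
                stacklevel=2,
            )
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if (self.fertility_case is FertilityCase.CASE2
                and self.L >= 2 * FERTILITY_END_AGE):
            raise ValueError(
                "omega_F = 2/(90 - L) is undefined for L >= 90 under case2"
            )

    @property
    def interbirth_interval(self) -> float:
        """Mean years between successive births, 1/beta."""
        return 1.0 / self.beta

    @property
    def pair_bond_duration(self) -> float:
        """Mean pair-bond length in years, 1/chi (inf when chi = 0)."""
        return math.inf if self.chi == 0 else 1.0 / self.chi

    def with_updates(self, **kwargs: Any) -> "ParameterSet":
        """Return a copy with some fields replaced.

        Accepts the aliases ``interbirth_interval`` (sets ``beta``) and
        ``pair_bond_duration`` (sets ``chi``) in addition to field names.
        """
        kwargs = _resolve_aliases(kwargs)
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        """Build a parameter set from a flat mapping.

        ``interbirth_interval`` is accepted as an alias for ``beta``
        (beta = 1/interval) and ``pair_bond_duration`` for ``chi``
        (chi = 1/duration).  Supplying an alias together with an
        inconsistent base value is an error.
        """
        return cls(**_resolve_aliases(dict(data)))

    def to_dict(self) -> dict[str, Any]:
        return {
            "rho": self.rho,
            "delta_g": self.delta_g,
            "k": self.k,
            "beta": self.beta,
            "q_star": self.q_star,
            "chi": self.chi,
            "L": self.L,
            "fertility_case": self.fertility_case.value,
            "male_mortality_factor": self.male_mortality_factor,
            "male_frailty_scale": self.male_frailty_scale,
        }


def _resolve_aliases(data: dict[str, Any]) -> dict[str, Any]:
    valid = set(ParameterSet.__dataclass_fields__) | {
        "interbirth_interval", "pair_bond_duration"}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    if "interbirth_interval" in data:
        interval = data.pop("interbirth_interval")
        if interval <= 0:
            raise ValueError("interbirth_interval must be positive")
        beta = 1.0 / interval
        if "beta" in data and not math.isclose(data["beta"], beta,
                                               rel_tol=1e-9):
            raise ValueError(
                f"beta={data['beta']} conflicts with "
                f"interbirth_interval={interval} (implies beta={beta})"
            )
        data["beta"] = beta
    if "pair_bond_duration" in data:
        duration = data.pop("pair_bond_duration")
        if duration <= 0:
            raise ValueError(
                "pair_bond_duration must be positive; use chi=0 for "
                "unbreakable bonds (infinite duration)"
            )
        chi = 0.0 if math.isinf(duration) else 1.0 / duration
        if "chi" in data and not math.isclose(data["chi"], chi,
                                              rel_tol=1e-9, abs_tol=0.0):
            raise ValueError(
                f"chi={data['chi']} conflicts with "
                f"pair_bond_duration={duration} (implies chi={chi})"
            )
        data["chi"] = chi
    return data


@dataclass(frozen=True)
class DerivedRates:
    """Rates computed from a :class:`ParameterSet`.

    omega_F
        Rate of female fertility loss, per year: 0 under case1, otherwise
        the reciprocal of the 45 - L/2 expected fertile years,
        2/(90 - L).
    omega_M
        Rate of male frailty (retirement from mate competition), per year:
        1/(male_frailty_scale * L).
    delta_m
        Death rate of multiple-mating dependants, k * delta_g.
    """

    omega_F: float
    omega_M: float
    delta_m: float


def derive_rates(params: ParameterSet) -> DerivedRates:
    """Compute the fertility-loss, frailty and dependant-mortality rates."""
    if params.fertility_case is FertilityCase.CASE1:
        omega_F = 0.0
    else:
        omega_F = 2.0 / (2 * FERTILITY_END_AGE - params.L)
    omega_M = 1.0 / (params.male_frailty_scale * params.L)
    delta_m = params.k * params.delta_g
    return DerivedRates(omega_F=omega_F, omega_M=omega_M, delta_m=delta_m)
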