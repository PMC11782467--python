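"""Independent oracles for the test suite.

Two deliberately separate routes to the same model:

* :func:`flux_rhs` builds the derivative from an explicit enumeration of
  demographic events (matings, maturations, dependant deaths, fertility
  loss, break-ups, retirement, adult deaths), never from the closed-form
  per-compartment equations the package implements.
* :func:`rk4_fixed` is a plain fixed-step classical Runge-Kutta
  integrator over that flux derivative.

Both are written for clarity, not speed, and are used only to check the
package's compiled right-hand side and adaptive integration.
"""
from __future__ import annotations

import numpy as np

NAMES = ["FM", "FG", "M", "G", "FMm", "FGg", "FGm", "FMg",
         "PGg", "PG", "PMm", "PMg", "PM", "X", "Xm", "Xg", "Y"]
IX = {n: i for i, n in enumerate(NAMES)}

PAIRS = ["PGg", "PG", "PMm", "PMg", "PM"]
SINGLES = [n for n in NAMES if n not in PAIRS]
CARERS = ["FMm", "FGg", "FGm", "FMg", "PGg", "PMm", "PMg", "Xg", "Xm"]
FEMALES = ["FM", "FG", "FMm", "FGm", "FMg", "FGg", "X", "Xm", "Xg"]


def mortality(y, beta, L, male_factor=1.09):
    s = dict(zip(NAMES, y))
    muF = max(1.0 / L, 0.5 * beta * sum(s[n] for n in CARERS))
    return muF, male_factor * muF


def flux_rhs(y, rho, beta, delta_m, delta_g, chi, q_star, omega_F,
             omega_M, L, male_factor=1.09):
    """Event-by-event construction of the 17-compartment derivative."""
    s = dict(zip(NAMES, y))
    muF, muM = mortality(y, beta, L, male_factor)
    MG = s["M"] + s["G"]
    fM = s["M"] / MG if MG > 0 else 0.0
    fG = s["G"] / MG if MG > 0 else 0.0
    q = fM * q_star

    d = np.zeros(len(NAMES))

    def ev(rate, *changes):
        for name, coef in changes:
            d[IX[name]] += rate * coef

    # matings (females drive; partner chosen in proportion to M vs G)
    ev(rho * fM * s["FM"], ("FM", -1), ("FMm", +1))
    ev(rho * fG * s["FM"] * 0.5, ("FM", -1), ("G", -1), ("PMm", +1))
    ev(rho * fG * s["FM"] * 0.5, ("FM", -1), ("G", -1), ("PMg", +1))
    ev(rho * fM * s["FG"] * 0.5, ("FG", -1), ("FGg", +1))
    ev(rho * fM * s["FG"] * 0.5, ("FG", -1), ("FGm", +1))
    ev(rho * fG * s["FG"], ("FG", -1), ("G", -1), ("PGg", +1))
    ev(rho * s["PG"], ("PG", -1), ("PGg", +1))
    ev(rho * s["PM"] * 0.5, ("PM", -1), ("PMm", +1))
    ev(rho * s["PM"] * 0.5, ("PM", -1), ("PMg", +1))

    # maturation: carer returns home; the dependant becomes one adult,
    # half daughter / half son; sons of guarded dependants are stolen by
    # the multiple-mating pool with probability q
    for src, home, dep in [("FMm", "FM", "m"), ("FGm", "FG", "m"),
                           ("PMm", "PM", "m"), ("Xm", "X", "m"),
                           ("FGg", "FG", "g"), ("FMg", "FM", "g"),
                           ("PGg", "PG", "g"), ("PMg", "PM", "g"),
                           ("Xg", "X", "g")]:
        r = beta * s[src]
        ev(r, (src, -1), (home, +1))
        if dep == "m":
            ev(r, ("FM", +0.5), ("M", +0.5))
        else:
            ev(r, ("FG", +0.5), ("M", +0.5 * q), ("G", +0.5 * (1 - q)))

    # dependant death: carer returns home alone
    for src, home, rate in [("FMm", "FM", delta_m), ("FGm", "FG", delta_m),
                            ("PMm", "PM", delta_m), ("Xm", "X", delta_m),
                            ("FGg", "FG", delta_g), ("FMg", "FM", delta_g),
                            ("PGg", "PG", delta_g), ("PMg", "PM", delta_g),
                            ("Xg", "X", delta_g)]:
        ev(rate * s[src], (src, -1), (home, +1))

    # female fertility loss; paired males rejoin the mating pool
    for src, dst in [("FM", "X"), ("FG", "X"), ("FMm", "Xm"),
                     ("FGm", "Xm"), ("FMg", "Xg"), ("FGg", "Xg")]:
        ev(omega_F * s[src], (src, -1), (dst, +1))
    for pair, dst in [("PM", "X"), ("PG", "X"), ("PMm", "Xm"),
                      ("PMg", "Xg"), ("PGg", "Xg")]:
        ev(omega_F * s[pair], (pair, -1), (dst, +1), ("G", +1))

    # pair break-up: female keeps any dependant, male rejoins the pool
    for pair, fdst in [("PM", "FM"), ("PG", "FG"), ("PMm", "FMm"),
                       ("PMg", "FMg"), ("PGg", "FGg")]:
        ev(chi * s[pair], (pair, -1), (fdst, +1), ("G", +1))

    # male frailty: retirement from the mating pool
    ev(omega_M * s["M"], ("M", -1), ("Y", +1))
    ev(omega_M * s["G"], ("G", -1), ("Y", +1))

    # adult deaths (a paired death frees the survivor)
    for f in FEMALES:
        ev(muF * s[f], (f, -1))
    for m in ["M", "G", "Y"]:
        ev(muM * s[m], (m, -1))
    for pair, fdst in [("PM", "FM"), ("PG", "FG"), ("PMm", "FMm"),
                       ("PMg", "FMg"), ("PGg", "FGg")]:
        ev(muM * s[pair], (pair, -1), (fdst, +1))
        ev(muF * s[pair], (pair, -1), ("G", +1))
    return d


def birth_death_tally(y, d, beta, L, male_factor=1.09):
    """(dN/dt from a derivative vector, births - deaths tallied directly).

    N counts individuals: singles once, pairs twice.  Births are the
    maturation flux out of the nine carer compartments; deaths are the
    mortality rates applied to every female- and male-containing
    compartment (pairs contributing one of each).
    """
    s = dict(zip(NAMES, y))
    n_dot = (sum(d[IX[n]] for n in SINGLES)
             + 2 * sum(d[IX[p]] for p in PAIRS))
    muF, muM = mortality(y, beta, L, male_factor)
    births = beta * sum(s[n] for n in CARERS)
    deaths = (muF * (sum(s[n] for n in FEMALES)
                     + sum(s[p] for p in PAIRS))
              + muM * (s["M"] + s["G"] + s["Y"]
                       + sum(s[p] for p in PAIRS)))
    return n_dot, births - deaths


def rk4_fixed(y0, rates, t_end, dt):
    """Classical fixed-step RK4 over the flux derivative."""
    y = np.asarray(y0, dtype=float).copy()
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = flux_rhs(y, **rates)
        k2 = flux_rhs(y + 0.5 * dt * k1, **rates)
        k3 = flux_rhs(y + 0.5 * dt * k2, **rates)
        k4 = flux_rhs(y + dt * k3, **rates)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def rates_from_params(params):
    """Map a package ParameterSet to the oracle's keyword rates."""
    from pairbond import derive_rates
    der = derive_rates(params)
    return dict(rho=params.rho, beta=params.beta, delta_m=der.delta_m,
                delta_g=params.delta_g, chi=params.chi,
                q_star=params.q_star, omega_F=der.omega_F,
                omega_M=der.omega_M, L=params.L,
                male_factor=params.male_mortality_factor)
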