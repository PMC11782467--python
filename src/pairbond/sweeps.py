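"""Parameter-plane sweeps: phase diagrams, boundaries and ratio curves.

A sweep runs one equilibrium simulation per cell of a 2-D parameter grid
(identical initial conditions in every cell) and records the dominant
strategy together with the equilibrium sex ratios.  The resulting region
map is the model's phase diagram; the transition between the guarding
and multiple-mating regions tracks curves of constant OSR, which is the
quantitative claim the sweep machinery exists to probe.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    Dominance,
    IntegrationError,
    IntegrationSettings,
    find_equilibrium,
)
from .model import PopulationState
from .params import ParameterSet

__all__ = [
    "AxisSpec",
    "RegionMap",
    "BoundaryRecord",
    "BoundarySet",
    "run_grid",
    "extract_boundary",
    "osr_curve",
    "guarding_fraction",
]

_SINGLE_STRATEGY = (Dominance.GUARDING, Dominance.MULTIPLE_MATING)


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: a parameter name and its ordered grid values.

    The name may be any :class:`ParameterSet` field or one of the
    aliases ``interbirth_interval`` (1/beta) and ``pair_bond_duration``
    (1/chi).  Values must be strictly monotone.
    """

    name: str
    values: tuple[float, ...]

    def __init__(self, name: str, values: Sequence[float]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "values", tuple(float(v) for v in values))
        if len(self.values) == 0:
            raise ValueError("axis needs at least one value")
        diffs = np.diff(self.values)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError(f"axis {name!r} values must be strictly "
                             "monotone")
        # fail fast on unknown names
        ParameterSet().with_updates(**{name: self.values[0]})

    def apply(self, base: ParameterSet, value: float) -> ParameterSet:
        return base.with_updates(**{self.name: value})


@dataclass(frozen=True)
class RegionMap:
    """Equilibrium outcomes over a 2-D parameter grid (phase diagram).

    Matrices are indexed ``[i, j]`` with ``i`` along ``axis1`` and ``j``
    along ``axis2``.  ``dominance`` holds :class:`Dominance` labels
    (None for cells whose integration failed), ``converged`` whether the
    equilibrium run met its tolerance.
    """

    axis1: AxisSpec
    axis2: AxisSpec
    dominance: np.ndarray
    osr: np.ndarray
    asr: np.ndarray
    converged: np.ndarray
    base: ParameterSet
    initial_total: float = 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.axis1.values), len(self.axis2.values))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, v1 in enumerate(self.axis1.values):
            for j, v2 in enumerate(self.axis2.values):
                dom = self.dominance[i, j]
                rows.append({
                    self.axis1.name: v1,
                    self.axis2.name: v2,
                    "dominance": dom.value if dom is not None else "",
                    "osr": self.osr[i, j],
                    "asr": self.asr[i, j],
                    "converged": bool(self.converged[i, j]),
                })
        return pd.DataFrame(rows)

    def metadata(self) -> dict:
        return {
            "axis1": {"name": self.axis1.name,
                      "values": list(self.axis1.values)},
            "axis2": {"name": self.axis2.name,
                      "values": list(self.axis2.values)},
            "base_parameters": self.base.to_dict(),
            "initial_total": self.initial_total,
        }

    def to_files(self, csv_path: str | Path,
                 json_path: str | Path | None = None) -> None:
        """Write the long-form CSV and (optionally) metadata JSON."""
        self.to_dataframe().to_csv(csv_path, index=False,
                                   float_format="%.12g")
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps(self.metadata(), indent=2))

    @classmethod
    def from_files(cls, csv_path: str | Path,
                   json_path: str | Path) -> "RegionMap":
        meta = json.loads(Path(json_path).read_text())
        axis1 = AxisSpec(meta["axis1"]["name"], meta["axis1"]["values"])
        axis2 = AxisSpec(meta["axis2"]["name"], meta["axis2"]["values"])
        df = pd.read_csv(csv_path, keep_default_na=False,
                         na_values=["nan", "NaN", ""])
        shape = (len(axis1.values), len(axis2.values))
        dominance = np.empty(shape, dtype=object)
        osr = np.full(shape, np.nan)
        asr = np.full(shape, np.nan)
        converged = np.zeros(shape, dtype=bool)
        i1 = {v: i for i, v in enumerate(axis1.values)}
        i2 = {v: j for j, v in enumerate(axis2.values)}
        for _, row in df.iterrows():
            i = i1[float(row[axis1.name])]
            j = i2[float(row[axis2.name])]
            label = row["dominance"]
            dominance[i, j] = (Dominance(label)
                               if isinstance(label, str) and label else None)
            osr[i, j] = float(row["osr"])
            asr[i, j] = float(row["asr"])
            converged[i, j] = bool(row["converged"])
        return cls(axis1=axis1, axis2=axis2, dominance=dominance,
                   osr=osr, asr=asr, converged=converged,
                   base=ParameterSet.from_dict(meta["base_parameters"]),
                   initial_total=meta.get("initial_total", 2.0))


@dataclass(frozen=True)
class BoundaryRecord:
    """Two adjacent cells with differing single-strategy labels."""

    cell_a: tuple[int, int]
    cell_b: tuple[int, int]
    midpoint: tuple[float, float]  # (axis1, axis2) coordinates
    osr: float  # mean of the two cells' equilibrium OSR
    asr: float


@dataclass(frozen=True)
class BoundarySet:
    """Dominance-boundary cells of a region map."""

    records: tuple[BoundaryRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def mean_osr(self) -> float:
        """Mean equilibrium OSR over all boundary-adjacent cell pairs."""
        if not self.records:
            return math.nan
        return float(np.mean([r.osr for r in self.records]))

    @property
    def mean_asr(self) -> float:
        if not self.records:
            return math.nan
        return float(np.mean([r.asr for r in self.records]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "i_a": r.cell_a[0], "j_a": r.cell_a[1],
            "i_b": r.cell_b[0], "j_b": r.cell_b[1],
            "axis1_mid": r.midpoint[0], "axis2_mid": r.midpoint[1],
            "osr": r.osr, "asr": r.asr,
        } for r in self.records],
            columns=["i_a", "j_a", "i_b", "j_b",
                     "axis1_mid", "axis2_mid", "osr", "asr"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False,
                                   float_format="%.12g")


def run_grid(
    base: ParameterSet,
    axis1: AxisSpec,
    axis2: AxisSpec,
    settings: IntegrationSettings | None = None,
    init: PopulationState | None = None,
    progress: bool | Callable[[int, int], None] = False,
) -> RegionMap:
    """One equilibrium run per grid cell, identical initial conditions.

    Per-cell integration failures are recorded (converged False, no
    dominance label) and never abort the sweep.  ``progress`` may be
    True for a tqdm bar or a callable ``f(done, total)``.
    """
    settings = settings or IntegrationSettings()
    init = init or PopulationState.default_initial()
    shape = (len(axis1.values), len(axis2.values))
    dominance = np.empty(shape, dtype=object)
    osr = np.full(shape, np.nan)
    asr = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)

    total = shape[0] * shape[1]
    bar = None
    if progress is True:
        from tqdm import tqdm
        bar = tqdm(total=total, desc="sweep", unit="cell")
    done = 0
    for i, v1 in enumerate(axis1.values):
        params_row = axis1.apply(base, v1)
        for j, v2 in enumerate(axis2.values):
            params = axis2.apply(params_row, v2)
            try:
                res = find_equilibrium(params, init=init, settings=settings)
            except IntegrationError:
                dominance[i, j] = None
            else:
                dominance[i, j] = res.dominance
                osr[i, j] = res.ratios.osr
                asr[i, j] = res.ratios.asr
                converged[i, j] = res.converged
            done += 1
            if bar is not None:
                bar.update(1)
            elif callable(progress):
                progress(done, total)
    if bar is not None:
        bar.close()
    return RegionMap(axis1=axis1, axis2=axis2, dominance=dominance,
                     osr=osr, asr=asr, converged=converged, base=base,
                     initial_total=init.total())


def extract_boundary(region_map: RegionMap) -> BoundarySet:
    """All adjacent cell pairs where the dominant strategy flips.

    Scans horizontally and vertically adjacent cells; a pair is on the
    boundary when both cells converged to different single-strategy
    labels (coexistence, extinction and unconverged cells are skipped).
    The boundary OSR/ASR is the arithmetic mean of the two cells' —
    matching the grid-resolution precision of the sweep itself.
    """
    n1, n2 = region_map.shape
    if n1 < 2 and n2 < 2:
        raise ValueError("boundary extraction needs at least 2 cells "
                         "along one axis")
    v1 = region_map.axis1.values
    v2 = region_map.axis2.values
    records = []

    def usable(i, j):
        return (region_map.converged[i, j]
                and region_map.dominance[i, j] in _SINGLE_STRATEGY)

    for i in range(n1):
        for j in range(n2):
            if not usable(i, j):
                continue
            for i2, j2 in ((i + 1, j), (i, j + 1)):
                if i2 >= n1 or j2 >= n2 or not usable(i2, j2):
                    continue
                if region_map.dominance[i, j] == region_map.dominance[i2, j2]:
                    continue
                records.append(BoundaryRecord(
                    cell_a=(i, j), cell_b=(i2, j2),
                    midpoint=(0.5 * (v1[i] + v1[i2]),
                              0.5 * (v2[j] + v2[j2])),
                    osr=0.5 * (region_map.osr[i, j]
                               + region_map.osr[i2, j2]),
                    asr=0.5 * (region_map.asr[i, j]
                               + region_map.asr[i2, j2]),
                ))
    return BoundarySet(records=tuple(records))


def refine_boundary(
    region_map: RegionMap,
    boundary: BoundarySet,
    iterations: int = 4,
    settings: IntegrationSettings | None = None,
    init: PopulationState | None = None,
) -> BoundarySet:
    """Sharpen boundary locations by bisection between adjacent cells.

    For each record, bisects along the parameter-space segment joining
    the two cells until the strategy flip is bracketed to the requested
    depth; the refined OSR/ASR is the mean over the final bracket.
    """
    settings = settings or IntegrationSettings()
    init = init or PopulationState.default_initial()
    a1, a2 = region_map.axis1, region_map.axis2
    refined = []
    for rec in boundary:
        (ia, ja), (ib, jb) = rec.cell_a, rec.cell_b
        pa = (a1.values[ia], a2.values[ja])
        pb = (a1.values[ib], a2.values[jb])

        def solve(point):
            params = a2.apply(a1.apply(region_map.base, point[0]), point[1])
            return find_equilibrium(params, init=init, settings=settings)
        ra = solve(pa)
        rb = solve(pb)
        for _ in range(iterations):
            mid = (0.5 * (pa[0] + pb[0]), 0.5 * (pa[1] + pb[1]))
            rm = solve(mid)
            if rm.dominance == ra.dominance:
                pa, ra = mid, rm
            else:
                pb, rb = mid, rm
        refined.append(BoundaryRecord(
            cell_a=rec.cell_a, cell_b=rec.cell_b,
            midpoint=(0.5 * (pa[0] + pb[0]), 0.5 * (pa[1] + pb[1])),
            osr=0.5 * (ra.ratios.osr + rb.ratios.osr),
            asr=0.5 * (ra.ratios.asr + rb.ratios.asr),
        ))
    return BoundarySet(records=tuple(refined))


def osr_curve(
    base: ParameterSet,
    varying: AxisSpec,
    fixed: tuple[str, float] | None = None,
    settings: IntegrationSettings | None = None,
    init: PopulationState | None = None,
) -> pd.DataFrame:
    """Equilibrium OSR/ASR along one parameter axis.

    Returns a frame with columns value, osr, asr, dominance, converged.
    ``fixed`` optionally pins another parameter first (the typical use
    fixes lifespan L and varies the interbirth interval, or vice versa).
    """
    if fixed is not None:
        base = base.with_updates(**{fixed[0]: fixed[1]})
    settings = settings or IntegrationSettings()
    init = init or PopulationState.default_initial()
    rows = []
    for v in varying.values:
        params = varying.apply(base, v)
        try:
            res = find_equilibrium(params, init=init, settings=settings)
        except IntegrationError:
            rows.append({"value": v, "osr": math.nan, "asr": math.nan,
                         "dominance": "", "converged": False})
        else:
            rows.append({"value": v, "osr": res.ratios.osr,
                         "asr": res.ratios.asr,
                         "dominance": res.dominance.value,
                         "converged": res.converged})
    return pd.DataFrame(rows)


def guarding_fraction(region_map: RegionMap) -> float:
    """Fraction of converged single-strategy cells won by guarding.

    NaN when the map has no converged single-strategy cell.
    """
    n1, n2 = region_map.shape
    guard = 0
    usable = 0
    for i in range(n1):
        for j in range(n2):
            if (region_map.converged[i, j]
                    and region_map.dominance[i, j] in _SINGLE_STRATEGY):
                usable += 1
                if region_map.dominance[i, j] is Dominance.GUARDING:
                    guard += 1
    if usable == 0:
        return math.nan
    return guard / usable
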