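"""Exponential clonal growth: doubling time, burden back-calculation, onset dating.

The model is deliberately simple -- constant doubling time ``c`` from a
single founding cell, so a clone observed at N cells on day t_obs began
doubling at

    t_onset = t_obs - c * log2(N).

Cumulative population doubling level (PDL) grows linearly in time under
this model; the doubling time is the reciprocal of the slope of PDL on
time.  The offset between the onsets of two equally fast clones whose
abundance ratio never exceeds r is bounded by c * log2(r): a 4:1 ratio
bound means the clones started within two doubling times of each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .errors import FitError, SchemaError

UM3_PER_CM3 = 1e12


@dataclass(frozen=True)
class GrowthRecord:
    """One passage: cells seeded, cells harvested, harvest day."""

    time: float
    cells_seeded: float
    cells_harvested: float

    def __post_init__(self):
        if self.cells_seeded <= 0 or self.cells_harvested <= 0:
            raise ValueError("cell counts must be positive")


@dataclass
class CloneDynamics:
    """Bundle of the fitted/derived growth quantities for a set of clones."""

    c: float
    c_ci: tuple[float, float]
    t_obs: float
    n_total: Optional[float] = None
    n_clone: Optional[dict[str, float]] = None
    t_onset: Optional[dict[str, float]] = None
    max_ratio: Optional[float] = None
    x_max: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "doubling_time_days": self.c,
            "doubling_time_ci": list(self.c_ci),
            "observation_day": self.t_obs,
            "total_cells": self.n_total,
            "clone_cells": self.n_clone,
            "onset_day": self.t_onset,
            "max_clone_ratio": self.max_ratio,
            "onset_offset_bound_days": self.x_max,
        }


def delta_pdl(cells_harvested: float, cells_seeded: float) -> float:
    """Change in population doubling level: log2(harvested / seeded).

    Additive across consecutive passages, so cumulative PDL is the sum of
    the per-passage increments.
    """
    if cells_harvested <= 0 or cells_seeded <= 0:
        raise ValueError("cell counts must be positive")
    return math.log2(cells_harvested / cells_seeded)


def cumulative_pdl(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """Cumulative PDL at each harvest time of a passage series."""
    times = [r.time for r in records]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("record times must be strictly increasing")
    cum, out = 0.0, []
    for r in records:
        cum += delta_pdl(r.cells_harvested, r.cells_seeded)
        out.append((r.time, cum))
    return pd.DataFrame(out, columns=["time", "cumulative_pdl"])


def fit_doubling_time(records: Sequence[GrowthRecord], confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Doubling time (days) with a confidence interval, from a passage series.

    Ordinary least squares of cumulative PDL on time; the slope s is the
    doubling rate (doublings/day) and c = 1/s.  The CI comes from the
    t-distribution interval of s, transformed through the monotone map
    s -> 1/s, i.e. (1/s_high, 1/s_low).
    """
    if len(records) < 3:
        raise FitError("need at least 3 growth records to fit a doubling time")
    pdl = cumulative_pdl(records)
    if pdl["time"].max() <= pdl["time"].min():
        raise FitError("records must span a positive time interval")
    fit = stats.linregress(pdl["time"], pdl["cumulative_pdl"])
    if fit.slope <= 0:
        raise FitError(f"non-positive fitted slope {fit.slope:.3g}: no doubling")
    tcrit = stats.t.ppf(0.5 + confidence / 2, len(records) - 2)
    s_lo = fit.slope - tcrit * fit.stderr
    s_hi = fit.slope + tcrit * fit.stderr
    if s_lo <= 0:
        raise FitError("slope CI crosses zero: doubling time unbounded")
    return 1.0 / fit.slope, (1.0 / s_hi, 1.0 / s_lo)


def tumor_cell_burden(volume_cm3: float, cell_volume_um3: float = 2000.0,
                      tumor_fraction: float = 0.5) -> float:
    """Total tumor cells from imaging volume.

    N = volume [cm^3] * 1e12 [um^3/cm^3] / cell volume [um^3] * tumor fraction.
    Defaults: 2000 um^3 per cell and 50% tumor content.
    """
    if volume_cm3 <= 0 or cell_volume_um3 <= 0:
        raise ValueError("volume and cell volume must be positive")
    if not 0 < tumor_fraction <= 1:
        raise ValueError("tumor_fraction must lie in (0, 1]")
    return volume_cm3 * UM3_PER_CM3 / cell_volume_um3 * tumor_fraction


def partition_by_ratio(n_total: float, ratio_a_to_b: float) -> tuple[float, float]:
    """Split a total burden between two clones at abundance ratio r = a:b."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if ratio_a_to_b <= 0:
        raise ValueError("ratio must be positive")
    r = ratio_a_to_b
    return n_total * r / (1 + r), n_total / (1 + r)


def expansion_onset(n_clone: float, c: float, t_obs: float) -> float:
    """Day a clone of N cells began doubling, assuming a single founding cell."""
    if n_clone < 1:
        raise ValueError("n_clone must be >= 1")
    if c <= 0:
        raise ValueError("doubling time must be positive")
    return t_obs - c * math.log2(n_clone)


def forward_projection(t_onset: float, c: float, t_query: float) -> float:
    """Cells at t_query for a clone founded by one cell at t_onset (inverse of onset)."""
    if c <= 0:
        raise ValueError("doubling time must be positive")
    if t_query < t_onset:
        raise ValueError("t_query must be >= t_onset")
    return 2.0 ** ((t_query - t_onset) / c)


def onset_offset_bound(max_ratio: float, c: float) -> float:
    """Maximal onset offset x (days) between two equally fast clones.

    If their abundance ratio never exceeds max_ratio, then
    x < c * log2(max_ratio); a 4:1 bound gives exactly two doubling times.
    """
    if max_ratio < 1:
        raise ValueError("max_ratio must be >= 1")
    if c <= 0:
        raise ValueError("doubling time must be positive")
    return c * math.log2(max_ratio)


def derive_onset_offset_bound(max_ratio=4):
    """Symbolic derivation of the onset-offset bound, in doubling times.

    Solves 2**((t+x)/c) / 2**(t/c) < r for x and returns the bound x/c as
    an exact sympy expression (log2(r); equal to the integer 2 when r=4).
    """
    import sympy

    t, x = sympy.symbols("t x", real=True)
    c = sympy.symbols("c", positive=True)
    r = sympy.nsimplify(max_ratio)
    ratio = sympy.powsimp(2 ** ((t + x) / c) / 2 ** (t / c))  # -> 2**(x/c)
    # 2**(x/c) < r  <=>  x < c*log2(r); solve the boundary equation for x
    boundary = sympy.solve(sympy.Eq(ratio, r), x)
    assert len(boundary) == 1
    return sympy.simplify(boundary[0] / c)  # bound on x in units of c


def read_growth_tsv(path: str | Path) -> list[GrowthRecord]:
    """Read a growth-record TSV with columns [day, cells_seeded, cells_harvested]."""
    df = pd.read_csv(path, sep="\t")
    missing = {"day", "cells_seeded", "cells_harvested"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    try:
        return [GrowthRecord(float(r.day), float(r.cells_seeded), float(r.cells_harvested))
                for r in df.itertuples()]
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed growth record: {exc}") from exc


def write_growth_tsv(records: Sequence[GrowthRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.time, r.cells_seeded, r.cells_harvested) for r in records],
        columns=["day", "cells_seeded", "cells_harvested"],
    ).to_csv(path, sep="\t", index=False)
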