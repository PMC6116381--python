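"""Generation accounting and mutation-rate estimation for MA lines.

Generations per single-colony passage are log2 of the colony cell count
(a 2^27-cell colony is 27 generations). Colony sizes are measured at a
few bottlenecks and each measurement is applied to a window of passages;
the per-line total G is the window-weighted sum. Rates are mutations per
nucleotide per generation, mu = m / (G * L), summarized per group as
mean +/- 95% CL where the CL half-width is SEM times the critical value
of the t distribution at df = n - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def generations_per_passage(colony_cells: float) -> float:
    """log2 of the cell count of a single colony."""
    if colony_cells < 1:
        raise ValueError("colony_cells must be >= 1")
    return math.log2(colony_cells)


def default_measurement_map(
    measurement_bottlenecks: list[int], n_bottlenecks: int
) -> dict[int, int]:
    """Window sizes implied by measurement bottlenecks.

    Each measurement covers the passages from its own bottleneck up to
    (but excluding) the next measurement; the last runs to
    ``n_bottlenecks``. Measurements at 1, 11, 21 with 30 bottlenecks give
    windows 1-10, 11-20 and 21-30 of 10 passages each.
    """
    ms = sorted(measurement_bottlenecks)
    if not ms:
        raise ValueError("need at least one measurement bottleneck")
    if ms[0] != 1:
        raise ValueError("first measurement must be at bottleneck 1 (uncovered passages)")
    if ms[-1] > n_bottlenecks:
        raise ValueError("measurement bottleneck beyond n_bottlenecks")
    bounds = ms + [n_bottlenecks + 1]
    return {m: bounds[i + 1] - bounds[i] for i, m in enumerate(ms)}


def total_generations(
    colony_cells: dict[int, float],
    n_bottlenecks: int = 30,
    measurement_map: dict[int, int] | None = None,
) -> float:
    """Window-weighted total generations for one line.

    ``colony_cells`` maps measurement bottleneck -> colony cell count;
    ``measurement_map`` maps measurement bottleneck -> number of passages
    it covers (derived from the measurement schedule when omitted). Every
    passage must be covered by exactly one window.
    """
    if measurement_map is None:
        measurement_map = default_measurement_map(sorted(colony_cells), n_bottlenecks)
    missing = set(measurement_map) - set(colony_cells)
    if missing:
        raise ValueError(f"no colony count for measurement bottleneck(s) {sorted(missing)}")
    if sum(measurement_map.values()) != n_bottlenecks:
        raise ValueError(
            f"windows cover {sum(measurement_map.values())} passages, "
            f"expected {n_bottlenecks}"
        )
    return float(sum(
        generations_per_passage(colony_cells[m]) * size
        for m, size in measurement_map.items()
    ))


@dataclass
class LineGenerationRecord:
    """Colony-size record and derived generation count for one MA line."""

    line_id: str
    colony_cells: dict[int, float]          # measurement bottleneck -> cells
    n_bottlenecks: int = 30
    measurement_map: dict[int, int] | None = None
    generations_per_window: dict[int, float] = field(init=False)
    total_generations: float = field(init=False)

    def __post_init__(self) -> None:
        mm = self.measurement_map or default_measurement_map(
            sorted(self.colony_cells), self.n_bottlenecks
        )
        self.measurement_map = mm
        self.generations_per_window = {
            m: generations_per_passage(self.colony_cells[m]) * size
            for m, size in mm.items()
        }
        self.total_generations = total_generations(
            self.colony_cells, self.n_bottlenecks, mm
        )


def growth_rate(colony_cells: float, incubation_hours: float) -> float:
    """Generations per hour during one incubation round."""
    if incubation_hours <= 0:
        raise ValueError("incubation_hours must be > 0")
    return generations_per_passage(colony_cells) / incubation_hours


def mutation_rate(m: float, generations: float, sites: float) -> float:
    """Mutations per nucleotide per generation: m / (G * L)."""
    if generations <= 0:
        raise ValueError("generations must be > 0")
    if sites <= 0:
        raise ValueError("sites must be > 0")
    if m < 0:
        raise ValueError("mutation count must be >= 0")
    return m / (generations * sites)


@dataclass(frozen=True)
class RateEstimate:
    """Group summary with the mean +/- 95% CL convention."""

    category: str
    n: int
    mean: float
    sem: float
    cl_halfwidth: float

    @property
    def ci(self) -> tuple[float, float]:
        return self.mean - self.cl_halfwidth, self.mean + self.cl_halfwidth


def rate_summary(values, category: str = "") -> RateEstimate:
    """Mean, SEM and 95% CL half-width (SEM x t_crit, df = n-1)."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 values (SEM undefined for n < 2)")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    t_crit = float(stats.t.ppf(0.975, df=n - 1))
    return RateEstimate(category=category, n=n, mean=mean, sem=sem,
                        cl_halfwidth=sem * t_crit)


def per_line_rate_table(
    counts: pd.DataFrame,
    line_groups: dict[str, str],
    generations: dict[str, float],
    sites: float,
    categories: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-line rates: (group, line_id, category, m, G, L, rate).

    ``counts`` is the per-line table from the spectrum module; L defaults
    to the genome length but a depth-qualified (callable) site count can
    be passed instead. Every category uses the same G and L denominators,
    so per-category rates sum to the rate of the union category.
    """
    cats = categories or list(counts.columns)
    rows = []
    for lid, row in counts.iterrows():
        G = generations[lid]
        for cat in cats:
            m = int(row[cat])
            rows.append(dict(
                group=line_groups[lid], line_id=lid, category=cat,
                m=m, G=G, L=sites, rate=mutation_rate(m, G, sites),
            ))
    return pd.DataFrame(rows)


def summarize_rates(rate_table: pd.DataFrame) -> pd.DataFrame:
    """Group x category summaries (mean, SEM, 95% CL half-width, n)."""
    rows = []
    for (group, cat), sub in rate_table.groupby(["group", "category"], sort=False):
        est = rate_summary(sub["rate"], category=cat)
        rows.append(dict(
            group=group, category=cat, n=est.n, mean=est.mean, sem=est.sem,
            cl95=est.cl_halfwidth,
        ))
    return pd.DataFrame(rows)
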