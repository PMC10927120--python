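"""Homologous-group population tables, normalization and enrichment testing.

Assigned domains are tallied by homologous group and stratum (species or
kingdom), rolled up to architecture/class via the reference catalog, and
compared between an observed and a reference set with per-group 2x2
chi-squared tests under a Bonferroni-corrected significance level.

The chi-squared statistic is the closed-form Pearson statistic without a
continuity correction, with a 1-df upper-tail p-value; degenerate tables
(a zero margin) yield chi2 = 0, p = 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ClassifiedRegion, ReferenceCatalog, RegionLabel

__all__ = [
    "PopulationTable",
    "ComparisonRow",
    "tally_populations",
    "stratified_normalize",
    "chi2_2x2",
    "bonferroni_significant",
    "compare_sets",
]


@dataclass
class PopulationTable:
    """Counts of assigned domains: rows = strata, columns = h_groups."""

    counts: pd.DataFrame  # index: stratum, columns: h_group, values: int
    meta: dict  # h_group -> (class5, architecture)

    @property
    def strata(self) -> list:
        return list(self.counts.index)

    @property
    def groups(self) -> list:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def group_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def stratum_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Per-stratum relative populations (rows sum to 1)."""
        totals = self.stratum_totals().replace(0, np.nan)
        return self.counts.div(totals, axis=0).fillna(0.0)

    def rollup(self, level: str = "class5") -> pd.DataFrame:
        """Counts aggregated to class5 or architecture via catalog metadata."""
        pos = {"class5": 0, "architecture": 1}[level]
        key = {g: self.meta[g][pos] for g in self.groups}
        return self.counts.T.groupby(key).sum().T


def tally_populations(
    regions: Sequence[ClassifiedRegion],
    catalog: ReferenceCatalog,
    strata: Optional[dict] = None,
    strata_by: str = "species",
) -> PopulationTable:
    """Count ASSIGNED regions per (h_group, stratum).

    ``strata`` maps model_id to a stratum label (a species name or a kingdom);
    models absent from the map fall into a single "all" stratum. Only
    ASSIGNED regions contribute; an assigned region whose h_group is not in
    the catalog is an error.
    """
    meta = catalog.group_meta()
    rows = []
    for r in regions:
        if r.label is not RegionLabel.ASSIGNED:
            continue
        if r.h_group not in meta:
            raise ValueError(f"assigned region with unknown h_group {r.h_group!r}")
        stratum = (strata or {}).get(r.model_id, "all")
        rows.append((stratum, r.h_group))
    if not rows:
        counts = pd.DataFrame(dtype=int)
    else:
        df = pd.DataFrame(rows, columns=["stratum", "h_group"])
        counts = (
            df.value_counts()
            .unstack(fill_value=0)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
    return PopulationTable(counts=counts, meta=meta)


def stratified_normalize(table: PopulationTable) -> pd.DataFrame:
    """Observed/expected ratio under row-column independence.

    value(s, h) = count(s, h) * T / (row_total(s) * col_total(h)), the count
    normalized by total stratum and homologous-group population; cells with a
    zero margin are 0.
    """
    T = table.total
    if T == 0:
        raise ValueError("empty population table")
    counts = table.counts.astype(float)
    row = table.stratum_totals().astype(float)
    col = table.group_totals().astype(float)
    denom = np.outer(row, col)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom > 0, counts.values * T / denom, 0.0)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def chi2_2x2(a: float, b: float, c: float, d: float) -> Tuple[float, float]:
    """Pearson chi-squared for the 2x2 table [[a, b], [c, d]].

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with no continuity
    correction; p is the 1-df upper tail. A zero margin gives (0, 1).
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be >= 0")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def bonferroni_significant(p: float, alpha: float, m: int) -> bool:
    """Per-test decision at the family-wise level alpha over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < alpha / m


@dataclass
class ComparisonRow:
    group_id: str
    count_obs: int
    total_obs: int
    count_ref: int
    total_ref: int
    chi2: float
    p: float
    significant: bool


def compare_sets(
    obs: PopulationTable,
    ref: PopulationTable,
    alpha: float = 0.05,
    m_mode: str = "observed",
) -> List[ComparisonRow]:
    """Per-group 2x2 enrichment tests of observed vs reference populations.

    For each group in the union of both tables the 2x2 table is
    [count_obs, total_obs - count_obs; count_ref, total_ref - count_ref].
    The Bonferroni divisor m counts groups present (count > 0) in the
    observed set (``m_mode="observed"``, the default) or in the union
    (``m_mode="union"``). Rows are sorted by p ascending, ties by group id.
    """
    if obs.total == 0:
        raise ValueError("empty observed table")
    obs_counts = obs.group_totals()
    ref_counts = ref.group_totals()
    universe = sorted(set(obs_counts.index) | set(ref_counts.index))
    total_obs = int(obs_counts.sum())
    total_ref = int(ref_counts.sum())
    if m_mode == "observed":
        m = int((obs_counts > 0).sum())
    elif m_mode == "union":
        m = len(universe)
    else:
        raise ValueError(f"unknown m_mode {m_mode!r}")
    rows = []
    for g in universe:
        a = int(obs_counts.get(g, 0))
        c = int(ref_counts.get(g, 0))
        chi2, p = chi2_2x2(a, total_obs - a, c, total_ref - c)
        rows.append(ComparisonRow(
            group_id=g, count_obs=a, total_obs=total_obs,
            count_ref=c, total_ref=total_ref,
            chi2=chi2, p=p,
            significant=bonferroni_significant(p, alpha, m),
        ))
    rows.sort(key=lambda r: (r.p, r.group_id))
    return rows


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
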