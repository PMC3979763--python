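"""Contingency tables relating differential expression to binding-site
presence, and the associated enrichment statistics.

The central analysis asks whether genes called differentially expressed
after knockdown carry a binding-site peak within a TSS window more often
than expressed non-DE genes: a 2x2 table (with-site/without-site x
DE/non-DE) tested by a Pearson chi-square (df=1, two-tailed, no continuity
correction by default), with Fisher's exact test and the Mann-Whitney U
available for small-count and rank comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "build_contingency",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "mann_whitney",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts: rows with-site/without-site, columns selected-DE/non-DE.

    a = DE with site, b = non-DE with site, c = DE without, d = non-DE without.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("with_site", "without_site")
    col_labels: tuple[str, str] = ("de", "non_de")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be >= 0")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def column_proportions(self) -> tuple[float, float]:
        """Fraction with a site in each column (DE, non-DE)."""
        return self.a / (self.a + self.c), self.b / (self.b + self.d)


@dataclass
class EnrichmentResult:
    table: ContingencyTable2x2
    chi2: float
    df: int
    p_two_tailed: float
    odds_ratio: float

    @property
    def proportions(self) -> tuple[float, float]:
        return self.table.column_proportions


def build_contingency(
    de_calls: pd.DataFrame,
    gene_peak_map: dict,
    expressed_universe,
    direction: str = "all",
) -> ContingencyTable2x2:
    """Cross-tabulate binding-site presence against DE status.

    ``de_calls`` is the :func:`~silencescan.diffexpr.call_de` table;
    ``gene_peak_map`` maps gene_id to associated peaks;
    ``expressed_universe`` is the set of genes the analysis is restricted to
    (expressed genes after any annotation filtering). Columns are the
    selected DE genes (``direction`` in all/up/down) versus expressed non-DE
    genes; genes outside the universe are excluded.
    """
    if direction not in ("all", "up", "down"):
        raise ValueError(f"invalid direction {direction!r}")
    universe = [g for g in expressed_universe]
    if not universe:
        raise ValueError("empty expressed universe")
    status = de_calls["status"].reindex(universe)
    wanted = ("up", "down") if direction == "all" else (direction,)
    is_de = status.isin(wanted)
    is_non_de = status == "not_de"
    has_site = pd.Series(
        [g in gene_peak_map and len(gene_peak_map[g]) > 0 for g in universe],
        index=universe,
    )
    return ContingencyTable2x2(
        a=int((is_de & has_site).sum()),
        b=int((is_non_de & has_site).sum()),
        c=int((is_de & ~has_site).sum()),
        d=int((is_non_de & ~has_site).sum()),
        col_labels=(f"de_{direction}", "non_de"),
    )


def chi_square_2x2(
    table: ContingencyTable2x2, continuity: bool = False
) -> EnrichmentResult:
    """Pearson chi-square (df=1) with expected counts from the margins.

    Two-tailed p from the upper chi-square tail. No Yates continuity
    correction by default (flag available). Zero margins are an error;
    odds ratio = ad/bc (inf when bc = 0).
    """
    obs = table.as_array()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _exp = stats.chi2_contingency(obs, correction=continuity)
    bc = table.b * table.c
    odds = (table.a * table.d) / bc if bc else float("inf")
    return EnrichmentResult(table, float(chi2), int(df), float(p), float(odds))


def fisher_exact_2x2(table: ContingencyTable2x2, method: str = "point") -> float:
    """Two-sided Fisher exact p-value.

    ``method='point'`` sums hypergeometric probabilities <= that of the
    observed table (standard practice, scipy's two-sided); ``method='double'``
    doubles the smaller one-sided tail, capped at 1.
    """
    obs = table.as_array()
    if method == "point":
        return float(stats.fisher_exact(obs, alternative="two-sided")[1])
    if method == "double":
        less = stats.fisher_exact(obs, alternative="less")[1]
        greater = stats.fisher_exact(obs, alternative="greater")[1]
        return float(min(1.0, 2.0 * min(less, greater)))
    raise ValueError(f"unknown method {method!r}")


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    Exact two-sided p by enumeration when min(n_a, n_b) <= 8 and the pooled
    data is tie-free; otherwise the normal approximation with tie correction
    (and continuity correction). Returns (U of sample_a, p).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
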