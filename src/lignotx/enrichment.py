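"""Chi-square enrichment of functional categories in transcript groups.

Each (category, group) pair is tested with an independent Pearson chi-square
on the 2x2 table (in group / not in group) x (in category / not in category)
over the genome universe of annotated genes, without multiple-testing
correction by default. Tables with an expected cell below 1 are flagged and
additionally get a Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import GeneAnnotation


def chi2_2x2(table: np.ndarray | Sequence[Sequence[float]], yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and p (1 df) for a 2x2 contingency table.

    With ``yates=True`` the continuity correction is applied. A table with a
    zero row or column margin carries no information: statistic 0, p 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("chi2_2x2 needs a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), float(p)


@dataclass
class EnrichmentResult:
    """One category-in-group enrichment test against the genome background."""

    category: str
    group: str
    observed: int
    group_size: int
    genome_category_count: int
    genome_size: int
    expected: float
    chi2_statistic: float
    p_value: float
    percent_of_category: float
    low_expected: bool = False
    p_fisher: float | None = None

    def as_dict(self) -> dict:
        return {
            "category": self.category,
            "group": self.group,
            "observed": self.observed,
            "group_size": self.group_size,
            "genome_category_count": self.genome_category_count,
            "genome_size": self.genome_size,
            "expected": self.expected,
            "chi2": self.chi2_statistic,
            "p": self.p_value,
            "percent_of_category": self.percent_of_category,
            "low_expected": self.low_expected,
            "p_fisher": self.p_fisher,
        }


def chi_square_enrichment(
    group_genes: Iterable[str],
    annotation: GeneAnnotation,
    category: str,
    scheme: str = "funcat",
    universe: Iterable[str] | None = None,
    yates: bool = False,
) -> EnrichmentResult:
    """Test over/under-representation of one category in one gene group.

    The universe defaults to all genes in the annotation table ("all the
    annotated genes"); the group must be a subset of it. When any expected
    cell falls below 1 the chi-square approximation is unreliable: the result
    is flagged ``low_expected`` and carries a Fisher exact p as fallback.
    """
    members = annotation.in_category(category, scheme=scheme)
    if universe is None:
        universe_set = set(annotation.gene_ids)
    else:
        universe_set = set(universe)
    group_set = set(group_genes)
    if not group_set <= universe_set:
        extra = sorted(group_set - universe_set)[:10]
        raise ValueError(f"group genes outside the universe, e.g. {extra}")
    cat_set = {g for g, m in members.items() if m and g in universe_set}

    n = len(universe_set)
    gs = len(group_set)
    cat_n = len(cat_set)
    obs = len(group_set & cat_set)
    table = np.array(
        [[obs, gs - obs], [cat_n - obs, n - gs - (cat_n - obs)]], dtype=float
    )
    expected = gs * cat_n / n if n else 0.0
    chi2, p = chi2_2x2(table, yates=yates)

    exp_cells = np.outer(table.sum(axis=1), table.sum(axis=0)) / max(table.sum(), 1.0)
    low = bool((exp_cells < 1).any())
    p_fisher = None
    if low:
        _, p_fisher = stats.fisher_exact(table)
        p_fisher = float(p_fisher)

    return EnrichmentResult(
        category=category,
        group="",
        observed=obs,
        group_size=gs,
        genome_category_count=cat_n,
        genome_size=n,
        expected=float(expected),
        chi2_statistic=chi2,
        p_value=p,
        percent_of_category=100.0 * obs / cat_n if cat_n else 0.0,
        low_expected=low,
        p_fisher=p_fisher,
    )


SCREEN_GROUPS = ("A", "B", "C", "D", "E", "CONSTITUTIVE")


def enrichment_screen(
    assignments: pd.DataFrame,
    annotation: GeneAnnotation,
    scheme: str = "funcat",
    groups: Sequence[str] = SCREEN_GROUPS,
    bh: bool = False,
    yates: bool = False,
) -> pd.DataFrame:
    """One chi-square test per (category with >=1 genome member, group).

    Returns a tidy frame: category, group, observed, expected, chi2, p,
    percent_of_category, low_expected, p_fisher and optionally the
    Benjamini-Hochberg adjusted p column ``p_bh`` (off by default).
    """
    if scheme not in ("funcat", "kog", "cazy_family"):
        raise ValueError(f"unknown annotation scheme {scheme!r}")
    records = []
    universe = set(annotation.gene_ids)
    by_group = {
        g: [gene for gene in assignments.index[assignments["group"] == g] if gene in universe]
        for g in groups
    }
    for category in annotation.categories(scheme):
        for g in groups:
            res = chi_square_enrichment(
                by_group[g], annotation, category, scheme=scheme, yates=yates
            )
            res.group = g
            records.append(res.as_dict())
    out = pd.DataFrame.from_records(records)
    if bh and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
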