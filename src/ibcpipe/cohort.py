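"""Cohort-level burden and enrichment statistics.

Two-group comparisons between tumor cohorts: Fisher's exact test on 2x2
contingency tables of boolean traits (mutation status, hotspot status,
genome-doubling status) and Mann-Whitney rank tests on continuous
per-sample quantities (mutation burden, wGII). The two-sided Fisher
p-value follows the probability-ordering convention: the sum of
hypergeometric probabilities, over all tables with the observed margins,
that do not exceed the observed table's probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .errors import DomainError


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency table entries must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise DomainError("contingency table is empty")


def fisher_exact(table: ContingencyTable2x2 | list) -> float:
    """Two-sided Fisher's exact p-value (probability-ordering rule).

    Accepts a :class:`ContingencyTable2x2` or a nested list
    ``[[a, b], [c, d]]``. Enumerates all tables with the observed margins
    and sums the hypergeometric probabilities that are at most the observed
    table's probability (within relative tolerance 1e-7).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(min(probs[probs <= p_obs * (1 + 1e-7)].sum(), 1.0))


def mann_whitney(group_a, group_b, exact_limit: int = 20):
    """Two-sided Mann-Whitney test; returns ``(U, p)``.

    Rank-sum U with midranks for ties; the p-value uses exact enumeration
    for small tie-free samples (both groups <= ``exact_limit``) and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if max(a.size, b.size) <= exact_limit and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class SampleSummary:
    sample: str
    group: str
    burden: int
    wgii: float
    tp53_status: bool = False
    hotspot_status: bool = False
    wgd_status: bool = False
    age: float | None = None
    er_status: bool | None = None
    pgr_status: bool | None = None


def _trait_table(a_rows, b_rows, trait):
    a_pos = sum(1 for r in a_rows if getattr(r, trait))
    b_pos = sum(1 for r in b_rows if getattr(r, trait))
    return ContingencyTable2x2(a_pos, len(a_rows) - a_pos,
                               b_pos, len(b_rows) - b_pos)


def burden_table(group_a: list, group_b: list,
                 traits=("tp53_status", "hotspot_status", "wgd_status"),
                 continuous=("burden", "wgii")) -> pd.DataFrame:
    """Group-wise comparison report.

    Continuous quantities get means, SDs and Mann-Whitney p; boolean traits
    get the 2x2 counts and the Fisher p.
    """
    if not group_a or not group_b:
        raise DomainError("both cohorts must be non-empty")
    rows = []
    for quant in continuous:
        va = [getattr(r, quant) for r in group_a]
        vb = [getattr(r, quant) for r in group_b]
        u, p = mann_whitney(va, vb)
        rows.append({
            "measure": quant, "test": "mann_whitney",
            "mean_a": float(np.mean(va)), "sd_a": float(np.std(va, ddof=1)) if len(va) > 1 else 0.0,
            "mean_b": float(np.mean(vb)), "sd_b": float(np.std(vb, ddof=1)) if len(vb) > 1 else 0.0,
            "counts": f"n={len(va)} vs n={len(vb)}", "statistic": u, "p_value": p,
        })
    for trait in traits:
        t = _trait_table(group_a, group_b, trait)
        p = fisher_exact(t)
        rows.append({
            "measure": trait, "test": "fisher_exact",
            "mean_a": t.a / (t.a + t.b), "sd_a": np.nan,
            "mean_b": t.c / (t.c + t.d), "sd_b": np.nan,
            "counts": f"{t.a}/{t.a + t.b} vs {t.c}/{t.c + t.d}",
            "statistic": np.nan, "p_value": p,
        })
    return pd.DataFrame(rows)


def match_cohort(cases: list, pool: list, max_age_gap: float = 10.0):
    """Greedy one-to-one matching of cases to pool samples.

    For each case in input order, select (and remove from the pool) the
    candidate with identical ER and PgR status and the smallest age gap
    <= ``max_age_gap`` years. Returns ``(matches, unmatched)`` where
    ``matches`` is a list of (case, control) pairs.
    """
    available = list(pool)
    matches, unmatched = [], []
    for case in cases:
        best, best_gap = None, None
        for cand in available:
            if cand.er_status != case.er_status or cand.pgr_status != case.pgr_status:
                continue
            gap = abs(cand.age - case.age)
            if gap > max_age_gap:
                continue
            if best is None or gap < best_gap:
                best, best_gap = cand, gap
        if best is None:
            unmatched.append(case)
        else:
            available.remove(best)
            matches.append((case, best))
    return matches, unmatched


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH q-values, reported alongside raw p-values (never replacing them)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = p[i] * n / (rank_idx + 1)
        prev = min(prev, val)
        q[i] = prev
    return q
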