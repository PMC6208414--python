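"""Gene-family expansion statistics.

Two tests, both conditioning on total gene content:

* clade diversification — per family, a likelihood-ratio test on grouped
  binomial data (the two-level binomial GLM reduced to its closed form):
  the null fits one shared proportion of the proteome belonging to the
  family, the alternative fits separate focal-clade and comparison-clade
  proportions; 2*(l1 - l0) is referred to chi-square with 1 df.
* species expansion — per family and ordered pair of focal taxa, a
  one-sided Fisher exact test on the 2x2 table of (family members, other
  genes), upper tail, testing "first taxon's proportion larger".

Benjamini–Hochberg FDR is applied within each contrast type (the clade
sweep; the pooled pairwise sweep), and significance is called at an
FDR-adjusted p (q) below 0.01 by default, in the direction "larger" only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2, hypergeom
from statsmodels.stats.multitest import multipletests

from .family_analysis import FamilyCountMatrix, TaxonGrouping

__all__ = [
    "ExpansionResult",
    "fisher_exact_one_sided",
    "binomial_lrt",
    "bh_fdr",
    "test_clade_diversified",
    "test_species_expansion",
    "significant_families",
    "write_results_tsv",
]


@dataclass(frozen=True)
class ExpansionResult:
    """Outcome of one expansion test for one family and contrast."""

    family_id: str
    contrast: str
    statistic: float
    p_value: float
    q_value: float
    direction: int          # +1 focal/first larger, -1 smaller, 0 degenerate
    significant: bool


@lru_cache(maxsize=1_000_000)
def _hypergeom_upper(a: int, row1: int, col1: int, total: int) -> float:
    return float(hypergeom.sf(a - 1, total, col1, row1))


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Row 1 is (family members, other genes) in the first taxon, row 2 the
    same in the second; the p-value is P(X >= a) for the hypergeometric
    distribution with all margins fixed, i.e. the one-sided test that the
    first taxon's proportion is larger.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    return min(_hypergeom_upper(a, a + b, a + c, a + b + c + d), 1.0)


def binomial_lrt(
    counts: Sequence[int],
    totals: Sequence[int],
    focal: Sequence[bool],
) -> tuple[float, float, int]:
    """Grouped-binomial likelihood-ratio test of group-specific proportions.

    ``counts[i]`` of ``totals[i]`` genes of taxon i belong to the family;
    ``focal[i]`` labels the group.  Null: one shared proportion across all
    taxa; alternative: separate pooled proportions per group (their MLEs
    are pooled count/total).  Returns (statistic, p, direction) with the
    statistic referred to chi-square(1); all-zero counts degenerate to
    (0, 1, 0).
    """
    k = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    f = np.asarray(focal, dtype=bool)
    if not f.any() or f.all():
        raise ValueError("need at least one taxon in each group")
    if (n <= 0).any():
        raise ValueError("totals must be positive")
    if k.sum() == 0:
        return 0.0, 1.0, 0

    def ll(kk: float, nn: float) -> float:
        if nn == 0:
            return 0.0
        p = kk / nn
        return float(xlogy(kk, p) + xlogy(nn - kk, 1 - p))

    k_f, n_f = k[f].sum(), n[f].sum()
    k_c, n_c = k[~f].sum(), n[~f].sum()
    l_null = ll(k_f + k_c, n_f + n_c)
    l_alt = ll(k_f, n_f) + ll(k_c, n_c)
    stat = max(2.0 * (l_alt - l_null), 0.0)
    p = float(chi2.sf(stat, df=1))
    direction = int(np.sign(k_f / n_f - k_c / n_c))
    return stat, p, direction


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def test_clade_diversified(
    matrix: FamilyCountMatrix,
    grouping: TaxonGrouping,
    q_threshold: float = 0.01,
    method: str = "binomial",
) -> list[ExpansionResult]:
    """Per-family focal-vs-comparison clade diversification sweep.

    Outgroups are excluded from the contrast.  ``method='binomial'`` runs
    the grouped-binomial LRT (default); ``method='fisher'`` runs a pooled
    one-sided Fisher exact test instead.  BH-FDR is applied across all
    tested families; a family is significant iff q < threshold AND the
    focal clade is the larger side.  Families with zero members in both
    clades are skipped.
    """
    if not grouping.comparison_clade:
        raise ValueError("comparison clade is empty")
    focal = sorted(grouping.focal_clade)
    comp = sorted(grouping.comparison_clade)
    taxa = focal + comp
    mask = [True] * len(focal) + [False] * len(comp)
    totals = [matrix.taxon_totals[t] for t in taxa]

    tested: list[tuple[str, float, float, int]] = []
    for fam in matrix.families:
        counts = [int(matrix.counts.loc[fam, t]) for t in taxa]
        if sum(counts) == 0:
            continue
        if method == "binomial":
            stat, p, direction = binomial_lrt(counts, totals, mask)
        elif method == "fisher":
            k_f = sum(c for c, m in zip(counts, mask) if m)
            n_f = sum(t for t, m in zip(totals, mask) if m)
            k_c = sum(c for c, m in zip(counts, mask) if not m)
            n_c = sum(t for t, m in zip(totals, mask) if not m)
            p = fisher_exact_one_sided(k_f, n_f - k_f, k_c, n_c - k_c)
            stat = float(k_f / n_f - k_c / n_c)
            direction = int(np.sign(stat))
        else:
            raise ValueError(f"unknown method {method!r}")
        tested.append((fam, stat, p, direction))

    qs = bh_fdr([t[2] for t in tested])
    return [
        ExpansionResult(
            family_id=fam,
            contrast="focal_vs_comparison",
            statistic=stat,
            p_value=p,
            q_value=q,
            direction=direction,
            significant=bool(q < q_threshold and direction > 0),
        )
        for (fam, stat, p, direction), q in zip(tested, qs)
    ]


def test_species_expansion(
    matrix: FamilyCountMatrix,
    grouping: TaxonGrouping,
    q_threshold: float = 0.01,
    rule: str = "all",
) -> tuple[list[ExpansionResult], dict[str, set[str]]]:
    """Pairwise Fisher sweep for species-specific expansions in the focal clade.

    Families shared by >= 2 focal taxa are tested for every ordered pair of
    taxa in which the family occurs, on [[count_X, total_X - count_X],
    [count_Y, total_Y - count_Y]].  BH-FDR runs across ALL pairwise tests
    jointly.  With ``rule='all'`` (default) a family is declared expanded
    in X iff its test against every other occupied focal taxon is
    significant; ``rule='any'`` requires a single significant pair.

    Returns the full result list and the per-taxon expanded-family map.
    """
    focal = sorted(grouping.focal_clade)
    if len(focal) < 2:
        raise ValueError("need >= 2 focal taxa")
    totals = {t: matrix.taxon_totals[t] for t in focal}

    rows: list[tuple[str, str, str, float, int]] = []
    for fam in matrix.families:
        counts = {t: int(matrix.counts.loc[fam, t]) for t in focal}
        occupied = [t for t in focal if counts[t] >= 1]
        if len(occupied) < 2:
            continue
        for x, y in permutations(occupied, 2):
            a, b = counts[x], totals[x] - counts[x]
            c, d = counts[y], totals[y] - counts[y]
            p = fisher_exact_one_sided(a, b, c, d)
            direction = int(np.sign(a / totals[x] - c / totals[y]))
            rows.append((fam, x, y, p, direction))

    qs = bh_fdr([r[3] for r in rows])
    results = [
        ExpansionResult(
            family_id=fam,
            contrast=f"{x}>{y}",
            statistic=float("nan"),
            p_value=p,
            q_value=q,
            direction=direction,
            significant=bool(q < q_threshold),
        )
        for (fam, x, y, p, direction), q in zip(rows, qs)
    ]

    sig_pairs: dict[tuple[str, str], set[str]] = {}
    occupied_of: dict[str, set[str]] = {}
    for res, (fam, x, y, _p, _d) in zip(results, rows):
        occupied_of.setdefault(fam, set()).update((x, y))
        if res.significant:
            sig_pairs.setdefault((fam, x), set()).add(y)

    expanded: dict[str, set[str]] = {t: set() for t in focal}
    for fam, occ in occupied_of.items():
        for x in occ:
            beaten = sig_pairs.get((fam, x), set())
            others = occ - {x}
            ok = beaten >= others if rule == "all" else bool(beaten)
            if rule not in ("all", "any"):
                raise ValueError(f"unknown rule {rule!r}")
            if ok and others:
                expanded[x].add(fam)
    return results, expanded


def significant_families(results: Iterable[ExpansionResult]) -> set[str]:
    return {r.family_id for r in results if r.significant}


def write_results_tsv(results: Iterable[ExpansionResult],
                      path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("family_id\tcontrast\tstatistic\tp\tq\tdirection\t"
                 "significant\n")
        for r in results:
            fh.write(
                f"{r.family_id}\t{r.contrast}\t{r.statistic:.6g}\t"
                f"{r.p_value:.6g}\t{r.q_value:.6g}\t{r.direction}\t"
                f"{int(r.significant)}\n"
            )
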