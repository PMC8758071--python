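"""Comparison statistics linking synteny, GC3-50, copy number and methylation.

Implements the rank-based and exact tests used throughout the analysis:
Wilcoxon rank-sum comparisons of GC3-50 between gene classes (with an
exact small-sample path), Pearson/Spearman correlation of methylation
against GC3-50, 2%-lattice GC3-50 histograms, methylation curves binned
by GC3-50, and one-sided hypergeometric GO-term enrichment by synteny
class.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from syngc.methylation import GeneMethylation
from syngc.synteny import SyntenyStatus


@dataclass
class ComparisonResult:
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    median_x: float
    median_y: float
    mean_difference: float  # mean_x - mean_y
    statistic: float  # rank sum of sample x (midranks)
    p_value: float
    mode: str


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_two_sided_p(ranks2: np.ndarray, n_x: int, w2_obs: int) -> float:
    """Exact two-sided p for the rank-sum with ties, by tail enumeration.

    ``ranks2`` are doubled midranks (integers even with ties).  The
    distribution of the doubled rank-sum over all C(N, n_x) equally likely
    assignments is built with a subset-sum DP; the two-sided p-value is
    the probability of a rank-sum at least as far from its mean as the
    observed one.
    """
    n = len(ranks2)
    total = int(ranks2.sum())
    max_sum = total
    # counts[k, s] = number of k-subsets with doubled-rank-sum s
    counts = np.zeros((n_x + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        upper = min(n_x, n)
        for k in range(upper - 1, -1, -1):
            row = counts[k]
            if row.any():
                counts[k + 1, r:] += row[: max_sum + 1 - r]
    dist = counts[n_x]
    n_arr = dist.sum()
    mean2 = 2.0 * n_x * (n + 1) / 2.0  # doubled expected rank-sum
    dev = abs(w2_obs - mean2)
    sums = np.arange(max_sum + 1, dtype=float)
    p = dist[np.abs(sums - mean2) >= dev - 1e-9].sum() / n_arr
    return float(min(1.0, p))


def wilcoxon_rank_sum(
    sample_x: Sequence[float],
    sample_y: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    ``mode='exact'`` enumerates the permutation distribution of the
    rank-sum (ties handled through midranks); ``'normal-approx'`` uses the
    tie-corrected normal approximation with continuity correction;
    ``'auto'`` picks exact when the smaller sample has at most 10
    observations and the data are tie-free, else the approximation.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[: len(x)].sum())
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (min(len(x), len(y)) <= 10 and not has_ties) else "normal-approx"
    if mode == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)
        p = _exact_two_sided_p(ranks2, len(x), int(round(2 * w)))
        return w, p
    if mode != "normal-approx":
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> tuple[Optional[float], Optional[float]]:
    """Correlation coefficient and p-value; NA pairs dropped.

    Returns (None, None) when either vector has zero variance after
    dropping incomplete pairs.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(xa) == 0 or np.std(ya) == 0:
        return None, None
    if method == "pearson":
        r, p = sps.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = sps.spearmanr(xa, ya)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def compare_groups(
    values_x: Sequence[float],
    values_y: Sequence[float],
    label_x: str,
    label_y: str,
    mode: str = "auto",
) -> ComparisonResult:
    """Wilcoxon comparison of a metric between two gene groups."""
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    w, p = wilcoxon_rank_sum(x, y, mode=mode)
    used_mode = mode
    if mode == "auto":
        pooled = np.concatenate([x, y])
        tie_free = len(np.unique(pooled)) == len(pooled)
        used_mode = "exact" if (min(len(x), len(y)) <= 10 and tie_free) else "normal-approx"
    return ComparisonResult(
        label_x, label_y, len(x), len(y),
        float(np.mean(x)), float(np.mean(y)),
        float(np.median(x)), float(np.median(y)),
        float(np.mean(x) - np.mean(y)), w, p, used_mode,
    )


def gc3_50_distribution(
    gc3_values: Mapping[str, float], group_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group histogram of GC3-50 on its natural 2% lattice.

    Rows are bins 0,2,...,100 (percent); columns are groups; entries are
    gene counts.  Column sums equal the number of passing genes per group.
    """
    bins = np.arange(0, 102, 2)
    groups = sorted(set(group_labels.values()))
    table = pd.DataFrame(0, index=bins, columns=groups)
    table.index.name = "gc3_50_pct"
    for gid, v in gc3_values.items():
        label = group_labels.get(gid)
        if label is None or v is None or np.isnan(v):
            continue
        table.loc[int(round(v * 50)) * 2, label] += 1
    return table


@dataclass
class BinnedCurve:
    bin_pct: int
    context: str
    mean_level: Optional[float]
    n_genes: int
    n_context_sites: int
    shown: bool


def methylation_by_gc3_bins(
    gene_methylations: Mapping[str, GeneMethylation],
    gene_gc3: Mapping[str, float],
    context: str,
    min_sites: int = 200,
) -> list[BinnedCurve]:
    """Mean methylation per 2% GC3-50 bin for one context.

    A bin is flagged ``shown`` only when it accumulates at least
    ``min_sites`` covered context cytosines across its genes, suppressing
    noisy sparsely-covered bins.
    """
    per_bin: dict[int, list[GeneMethylation]] = {}
    for gid, gm in gene_methylations.items():
        v = gene_gc3.get(gid)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        per_bin.setdefault(int(round(v * 50)) * 2, []).append(gm)
    curves = []
    for b in sorted(per_bin):
        gms = per_bin[b]
        levels = [gm.levels.get(context) for gm in gms]
        levels = [v for v in levels if v is not None]
        sites = sum(gm.n_sites.get(context, 0) for gm in gms)
        curves.append(
            BinnedCurve(
                b, context,
                float(np.mean(levels)) if levels else None,
                len(gms), sites, sites >= min_sites,
            )
        )
    return curves


@dataclass
class EnrichmentRow:
    go_term: str
    species: str
    a: int  # term & syntenic
    b: int  # term & non-syntenic
    c: int  # other terms & syntenic
    d: int  # other terms & non-syntenic
    direction: str  # 'syntenic' or 'non-syntenic'
    p_value: float
    p_adjusted: float
    significant: bool


def go_enrichment(
    gene_go_map: Mapping[str, Iterable[str]],
    statuses: Mapping[str, SyntenyStatus],
    species: str,
    min_term_genes: int = 20,
    alpha: float = 0.01,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric GO enrichment by synteny class.

    The universe is the set of genes with both a GO annotation and a
    synteny status.  For each term annotating at least ``min_term_genes``
    of those genes, enrichment is tested one-sidedly in each direction and
    the more enriched direction reported; the significance flag uses the
    raw p-value at ``alpha`` (no multiple-testing correction), with
    Benjamini-Hochberg adjusted values carried in an extra column.
    """
    if not gene_go_map:
        raise ValueError("empty GO map")
    universe = [g for g in gene_go_map if g in statuses]
    n_syn = sum(1 for g in universe if statuses[g].syntenic)
    M = len(universe)
    term_genes: dict[str, list[str]] = {}
    for g in universe:
        for t in gene_go_map[g]:
            term_genes.setdefault(t, []).append(g)

    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        if len(genes) < min_term_genes:
            continue
        a = sum(1 for g in genes if statuses[g].syntenic)
        b = len(genes) - a
        c = n_syn - a
        d = (M - n_syn) - b
        # hypergeometric: drawing len(genes) annotated genes from M, n_syn syntenic
        p_syn = float(sps.hypergeom.sf(a - 1, M, n_syn, len(genes)))
        p_non = float(sps.hypergeom.sf(b - 1, M, M - n_syn, len(genes)))
        if p_syn <= p_non:
            direction, p = "syntenic", p_syn
        else:
            direction, p = "non-syntenic", p_non
        rows.append(EnrichmentRow(term, species, a, b, c, d, direction, p, np.nan, p < alpha))

    if rows:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, adj):
            r.p_adjusted = float(q)
    return rows


def cross_species_counts(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    """Per term and direction, the number of species significantly enriched."""
    tally: dict[tuple[str, str], int] = {}
    for r in rows:
        if r.significant:
            key = (r.go_term, r.direction)
            tally[key] = tally.get(key, 0) + 1
    df = pd.DataFrame(
        [(t, d, n) for (t, d), n in sorted(tally.items())],
        columns=["go_term", "direction", "n_species_significant"],
    )
    return df
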