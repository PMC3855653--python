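"""Reference-free clustering-quality metrics, N50, and significance tests.

Three proxy metrics judge a clustering without a reference genome:

* redundancy — distinct reference genes matched by cluster representatives
  and the mean number of representatives per matched gene (a ratio near 1
  indicates little cluster fragmentation);
* gene-family-size correlation — Pearson r between reference gene-family
  sizes and the family sizes inferred from representative best hits;
* single-copy fragmentation — how many conserved single-copy orthologs are
  matched by 1, 2, 3, >= 4 or no representatives.

A truth-based Adjusted Rand Index lives in :mod:`lstclust.synthetic` for
simulated data; the proxies above are what remains applicable to real
assemblies.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "redundancy_metrics",
    "family_size_correlation",
    "single_copy_fragmentation",
    "n50",
    "compare_clusterings",
    "chimera_candidates",
]

FRAGMENTATION_CATEGORIES = (">=4", "3", "2", "1", "absent")


def redundancy_metrics(rep_best_hits: Mapping[str, str]) -> tuple[int, float]:
    """(distinct reference genes matched, mean representatives per matched gene)."""
    if not rep_best_hits:
        return 0, float("nan")
    distinct = len(set(rep_best_hits.values()))
    return distinct, len(rep_best_hits) / distinct


def family_size_correlation(
    rep_families: Mapping[str, str] | Mapping[str, int],
    reference_family_sizes: Mapping[str, int],
    restrict_to: Iterable[str] | None = None,
) -> float:
    """Pearson r between reference and inferred gene-family size vectors.

    ``rep_families`` maps representative -> family id (counts are tallied)
    or family -> count directly.  The family universe is the union of keys;
    families absent on either side count 0.  ``restrict_to`` limits the
    universe (e.g. to families that grew or shrank between clusterings).
    """
    inferred: dict[str, int] = {}
    values = list(rep_families.values())
    if values and isinstance(values[0], int):
        inferred = dict(rep_families)  # type: ignore[arg-type]
    else:
        for fam in values:
            inferred[fam] = inferred.get(fam, 0) + 1
    universe = sorted(set(inferred) | set(reference_family_sizes))
    if restrict_to is not None:
        keep = set(restrict_to)
        universe = [f for f in universe if f in keep]
    if len(universe) < 2:
        warnings.warn("fewer than 2 families; correlation undefined")
        return float("nan")
    x = np.array([reference_family_sizes.get(f, 0) for f in universe], dtype=float)
    y = np.array([inferred.get(f, 0) for f in universe], dtype=float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in a family-size vector; correlation undefined")
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def single_copy_fragmentation(
    single_copy_genes: Iterable[str],
    rep_hits: Mapping[str, set[str] | Sequence[str]],
) -> dict[str, int]:
    """Counts of single-copy genes matched by >=4, 3, 2, 1 or no representatives.

    The categories partition the gene set.
    """
    table = {c: 0 for c in FRAGMENTATION_CATEGORIES}
    for gene in single_copy_genes:
        k = len(set(rep_hits.get(gene, ())))
        if k >= 4:
            table[">=4"] += 1
        elif k == 0:
            table["absent"] += 1
        else:
            table[str(k)] += 1
    return table


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L hold half the total bases."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    xs = sorted(lengths, reverse=True)
    half = sum(xs) / 2.0
    acc = 0
    for x in xs:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def compare_clusterings(
    metric_a: Sequence[float],
    metric_b: Sequence[float],
    paired: bool = True,
) -> float:
    """Two-sided t-test p-value comparing per-species metric vectors.

    Paired by default (one value per reference species in each clustering).
    Identical vectors give p = 1.0; a constant non-zero shift (zero variance
    of the differences) degenerates to p -> 0 with a warning.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison requires equal-length vectors")
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least two per-species values")
    if paired:
        diffs = a - b
        if np.all(diffs == 0):
            return 1.0
        if diffs.std(ddof=1) == 0:
            warnings.warn("zero variance of paired differences; p degenerates to 0")
            return 0.0
        return float(sps.ttest_rel(a, b).pvalue)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if np.allclose(a.mean(), b.mean()) else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def chimera_candidates(
    rep_hits_with_families: Mapping[str, Iterable[str]],
) -> list[str]:
    """Representatives whose qualifying hits span two or more gene families."""
    out = []
    for rep in sorted(rep_hits_with_families):
        fams = {f for f in rep_hits_with_families[rep] if f is not None}
        if len(fams) >= 2:
            out.append(rep)
    return out
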