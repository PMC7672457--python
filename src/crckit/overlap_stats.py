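"""Set-overlap statistics for multi-knockdown gene sets.

The empirical distribution test asks how often k gene sets, redrawn
uniformly without replacement from the expressed-gene universe at their
observed sizes, intersect at least as much as the real sets do. The k-way
intersection size under that null is sampled exactly by a chain of
hypergeometric draws (|S1 n S2| ~ HG(N, n1, n2); conditioning on that
intersection, the next set intersects it hypergeometrically, and so on),
which is distributionally identical to literal set resampling and
vectorizes to millions of permutations. The estimator p = (n_ge + 1) /
(n_perm + 1) never returns zero; reaching p < 1e-6 therefore needs at
least 1e6 permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .expression import GeneSet


@dataclass(frozen=True)
class OverlapResult:
    observed_intersection: int
    n_perm: int
    n_ge: int
    pvalue: float
    seed: int


def empirical_overlap_test(
    sets: list[GeneSet],
    universe: GeneSet,
    n_perm: int = 1_000_000,
    seed: int = 0,
) -> OverlapResult:
    """Permutation p-value for the size of the k-way intersection."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for s in sets:
        stray = s.genes - universe.genes
        if stray:
            raise ValueError(
                f"set {s.label} not within universe: {sorted(stray)[:5]}"
            )
    observed = len(frozenset.intersection(*(s.genes for s in sets)))
    n_universe = len(universe.genes)
    # canonical order (sizes descending) so the p-value is invariant to
    # the order the caller lists the sets in
    sizes = sorted((len(s) for s in sets), reverse=True)
    rng = np.random.default_rng(seed)
    inter = np.full(n_perm, sizes[0], dtype=np.int64)
    for size in sizes[1:]:
        inter = rng.hypergeometric(inter, n_universe - inter, size)
    n_ge = int(np.sum(inter >= observed))
    pvalue = (n_ge + 1) / (n_perm + 1)
    return OverlapResult(observed, n_perm, n_ge, pvalue, seed)


def shared_fraction(
    sets: list[GeneSet], require_all: bool = False
) -> dict[str, float]:
    """Per set, the fraction of its genes present in >= 1 other set
    (or in all other sets with ``require_all``). Empty sets give NaN with
    a warning."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    out: dict[str, float] = {}
    for i, s in enumerate(sets):
        others = [t.genes for j, t in enumerate(sets) if j != i]
        if not s.genes:
            warnings.warn(f"set {s.label} is empty; shared fraction undefined")
            out[s.label] = float("nan")
            continue
        if require_all:
            shared = s.genes & frozenset.intersection(*others)
        else:
            shared = s.genes & frozenset.union(*others)
        out[s.label] = len(shared) / len(s.genes)
    return out


def down_in_at_least_m(
    sets: list[GeneSet], pathway: GeneSet, m: int
) -> tuple[int, float]:
    """Genes of ``pathway`` appearing in >= m of the sets; returns the
    count and its fraction of the pathway."""
    if not (1 <= m <= len(sets)):
        raise ValueError("need 1 <= m <= number of sets")
    if not pathway.genes:
        raise ValueError("pathway is empty")
    count = sum(
        1
        for gene in pathway.genes
        if sum(gene in s.genes for s in sets) >= m
    )
    return count, count / len(pathway.genes)
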