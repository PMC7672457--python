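"""Promoter/enhancer annotation from histone-mark combinatorics and
combinatorial TF occupancy summaries.

Each H3K27ac peak is the backbone of one regulatory element. An element is a
putative promoter when it overlaps H3K4me3 but no H3K4me1 and sits within the
promoter window of a TSS (H3K4me3+/H3K27ac+/H3K4me1-), and a distal enhancer
when it overlaps H3K4me1 but no H3K4me3 (H3K4me3-/H3K27ac+/H3K4me1+);
elements matching neither pattern are dropped and counted. Occupancy is the
ordered bit vector of which factors' ChIP peaks overlap the element by at
least 1 bp in half-open coordinates (abutting peaks do not overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .core_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    SignalTrack,
)
from .intervals import IntervalSet
from .superenhancer import SuperEnhancer


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    element_class: str  # promoter | enhancer
    assigned_gene: str
    occupancy: tuple[bool, ...] = ()
    h3k27ac_mean: float = 0.0


@dataclass
class OccupancySummary:
    factors: list[str]
    per_class: dict[str, dict]  # class -> {total, bound, bound_percent, ...}


def _index_by_chrom(peaks: list[Peak]) -> dict[str, IntervalSet]:
    out: dict[str, IntervalSet] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    for chrom, ivs in by_chrom.items():
        out[chrom] = IntervalSet(ivs)
    return out


def classify_elements(
    h3k27ac: list[Peak],
    h3k4me3: list[Peak],
    h3k4me1: list[Peak],
    genes: list[GeneAnnotation],
    promoter_window_bp: int = 2000,
) -> tuple[list[RegulatoryElement], int]:
    """Classify each H3K27ac peak; returns (elements, n_dropped)."""
    me3 = _index_by_chrom(h3k4me3)
    me1 = _index_by_chrom(h3k4me1)
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort()
    elements: list[RegulatoryElement] = []
    dropped = 0
    for p in h3k27ac:
        iv = p.interval
        has_me3 = iv.chrom in me3 and me3[iv.chrom].overlaps_any(iv.start, iv.end)
        has_me1 = iv.chrom in me1 and me1[iv.chrom].overlaps_any(iv.start, iv.end)
        nearest_gene, nearest_dist = _nearest_tss(iv, tss_by_chrom.get(iv.chrom, []))
        if has_me3 and not has_me1 and nearest_dist <= promoter_window_bp:
            cls = "promoter"
        elif has_me1 and not has_me3:
            cls = "enhancer"
        else:
            dropped += 1
            continue
        elements.append(
            RegulatoryElement(iv, cls, nearest_gene, h3k27ac_mean=p.signal)
        )
    return elements, dropped


def _nearest_tss(
    iv: GenomicInterval, tss_list: list[tuple[int, str]]
) -> tuple[str, int]:
    if not tss_list:
        return "", np.iinfo(np.int64).max
    positions = np.array([t for t, _ in tss_list])
    dists = np.maximum(
        np.maximum(iv.start - positions, positions - (iv.end - 1)), 0
    )
    i = int(np.argmin(dists))
    return tss_list[i][1], int(dists[i])


def assign_occupancy(
    elements: list[RegulatoryElement],
    factor_peak_sets: dict[str, list[Peak]],
) -> list[RegulatoryElement]:
    """Set occupancy bit f iff >= 1 bp overlap with any peak of factor f."""
    factor_idx = {
        name: _index_by_chrom(peaks) for name, peaks in factor_peak_sets.items()
    }
    out = []
    for el in elements:
        bits = tuple(
            el.interval.chrom in factor_idx[name]
            and factor_idx[name][el.interval.chrom].overlaps_any(
                el.interval.start, el.interval.end
            )
            for name in factor_peak_sets
        )
        out.append(replace(el, occupancy=bits))
    return out


_CARDINALITY_NAMES = {0: "unbound", 1: "solo", 2: "dual", 3: "trio", 4: "quad"}


def occupancy_fractions(
    elements: list[RegulatoryElement], factors: list[str]
) -> OccupancySummary:
    """Per element class: bound fraction (percent, 1 decimal), counts per
    occupancy cardinality and per exact pattern."""
    if not elements:
        raise ValueError("no elements")
    per_class: dict[str, dict] = {}
    for cls in sorted({e.element_class for e in elements}):
        group = [e for e in elements if e.element_class == cls]
        total = len(group)
        bound = sum(1 for e in group if any(e.occupancy))
        by_card: dict[str, int] = {}
        by_pattern: dict[str, int] = {}
        for e in group:
            k = sum(e.occupancy)
            card = _CARDINALITY_NAMES.get(k, f"{k}-fold")
            by_card[card] = by_card.get(card, 0) + 1
            pattern = (
                "+".join(f for f, b in zip(factors, e.occupancy) if b) or "none"
            )
            by_pattern[pattern] = by_pattern.get(pattern, 0) + 1
        per_class[cls] = {
            "total": total,
            "bound": bound,
            "bound_percent": round(100.0 * bound / total, 1),
            "by_cardinality": by_card,
            "by_pattern": by_pattern,
        }
    return OccupancySummary(list(factors), per_class)


def signal_profile(
    groups: dict[str, list[RegulatoryElement]],
    track: SignalTrack,
    halfwidth_bp: int = 2000,
    bins: int = 100,
) -> dict[str, np.ndarray]:
    """Mean binned signal around element centers, per group.

    Each element contributes per-bin means of per-base track values over
    center +- halfwidth (uncovered bases count 0); the group profile is the
    mean across its elements. Empty groups give all-NaN profiles with a
    warning.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    window = 2 * halfwidth_bp
    if window % bins:
        raise ValueError("window must divide evenly into bins")
    per_bin = window // bins
    out: dict[str, np.ndarray] = {}
    for label, elements in groups.items():
        if not elements:
            warnings.warn(f"group {label} is empty")
            out[label] = np.full(bins, np.nan)
            continue
        acc = np.zeros(bins)
        for el in elements:
            center = (el.interval.start + el.interval.end) // 2
            positions = np.arange(center - halfwidth_bp, center + halfwidth_bp)
            values = track.values_at(el.interval.chrom, positions)
            acc += values.reshape(bins, per_bin).mean(axis=1)
        out[label] = acc / len(elements)
    return out


def se_overlap_by_class(
    groups: dict[str, list[RegulatoryElement]],
    ses: list[SuperEnhancer],
) -> dict[str, float]:
    """Fraction of each group's elements overlapping a super-enhancer."""
    super_ivs: dict[str, list[tuple[int, int]]] = {}
    for se in ses:
        if se.is_super:
            super_ivs.setdefault(se.interval.chrom, []).append(
                (se.interval.start, se.interval.end)
            )
    idx = {chrom: IntervalSet(ivs) for chrom, ivs in super_ivs.items()}
    out: dict[str, float] = {}
    for label, elements in groups.items():
        if not elements:
            out[label] = float("nan")
            continue
        n = sum(
            1
            for el in elements
            if el.interval.chrom in idx
            and idx[el.interval.chrom].overlaps_any(
                el.interval.start, el.interval.end
            )
        )
        out[label] = n / len(elements)
    return out


def expression_by_class(
    groups: dict[str, list[RegulatoryElement]],
    expr: ExpressionMatrix,
    sample_subset: list[str] | None = None,
    test_pairs: list[tuple[str, str]] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[tuple[str, str], float]]:
    """log2(TPM+1) of each group's assigned genes (deduplicated per group).

    Returns (values per group, quartiles per group, rank-test p-values for
    the requested group pairs). The group comparison is a two-sided
    rank-based test (exact for small samples, normal approximation above
    n=50); identical groups give p = 1 under exact tie handling.
    """
    samples = sample_subset or expr.samples
    values: dict[str, np.ndarray] = {}
    quartiles: dict[str, np.ndarray] = {}
    for label, elements in groups.items():
        genes = sorted(
            {e.assigned_gene for e in elements if e.assigned_gene in expr.values.index}
        )
        if not genes:
            warnings.warn(f"group {label} has no expressed genes")
            values[label] = np.array([])
            quartiles[label] = np.full(3, np.nan)
            continue
        tpm = expr.values.loc[genes, samples].mean(axis=1).to_numpy()
        vals = np.log2(tpm + 1.0)
        values[label] = vals
        quartiles[label] = np.percentile(vals, [25, 50, 75])
    pvals: dict[tuple[str, str], float] = {}
    for a, b in test_pairs or []:
        x, y = values[a], values[b]
        if len(x) == 0 or len(y) == 0:
            pvals[(a, b)] = float("nan")
        elif np.ptp(np.concatenate([x, y])) == 0:
            pvals[(a, b)] = 1.0  # all tied
        else:
            method = "exact" if max(len(x), len(y)) <= 50 and not (
                len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            ) else "asymptotic"
            pvals[(a, b)] = float(
                stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
            )
    return values, quartiles, pvals
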