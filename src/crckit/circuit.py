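"""TF-to-TF regulatory graph over extended super-enhancers and enumeration of
fully interconnected auto-regulatory loops.

A directed edge A -> B exists when A's motif has at least one hit inside one
of B's extended super-enhancer regions. Candidate circuit members must be
auto-regulated (a self edge) and must pass the fusion-driver constraint: a
qualifying driver element (a GGAA microsatellite run, or a driver PWM hit if
one is supplied) plus a driver ChIP peak within their region set. Circuits
are all maximal sets of such TFs in which every ordered pair -- self pairs
included -- carries an edge; on the mutual-support graph these are exactly
the maximal cliques (Bron-Kerbosch with pivoting via networkx).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core_io import GenomicInterval, Peak, PositionWeightMatrix
from .intervals import IntervalSet, merge_within_gap
from .motifscan import MotifHit, scan_ggaa, scan_pwm


@dataclass
class CircuitGraph:
    nodes: list[str]
    regions: dict[str, list[GenomicInterval]]
    edges: dict[tuple[str, str], list[MotifHit]]
    auto: set[str] = field(default_factory=set)
    driver_ok: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class Circuit:
    members: frozenset[str]
    size: int
    total_evidence: int


def extend_regions(
    intervals: list[GenomicInterval],
    extension_bp: int,
    chrom_lengths: dict[str, int],
) -> list[GenomicInterval]:
    """Grow each interval by extension_bp on both sides, clamp to the
    chromosome, and merge overlaps."""
    if extension_bp < 0:
        raise ValueError("extension_bp must be >= 0")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if iv.chrom not in chrom_lengths:
            raise KeyError(f"unknown chromosome: {iv.chrom}")
        length = chrom_lengths[iv.chrom]
        by_chrom.setdefault(iv.chrom, []).append(
            (max(0, iv.start - extension_bp), min(length, iv.end + extension_bp))
        )
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        for s, e in merge_within_gap(by_chrom[chrom], gap=0):
            out.append(GenomicInterval(chrom, s, e))
    return out


def driver_constraint(
    regions: list[GenomicInterval],
    genome: dict[str, str],
    driver_peaks: list[Peak],
    ggaa_min_units: int = 4,
    driver_pwm: PositionWeightMatrix | None = None,
    pvalue_threshold: float = 1e-4,
) -> bool:
    """True iff the region set contains a qualifying driver motif (GGAA run
    of >= ggaa_min_units, or a driver PWM hit when one is supplied) and
    overlaps >= 1 bp of a driver ChIP peak."""
    peak_sets: dict[str, IntervalSet] = {}
    for chrom in {p.interval.chrom for p in driver_peaks}:
        peak_sets[chrom] = IntervalSet(
            [
                (p.interval.start, p.interval.end)
                for p in driver_peaks
                if p.interval.chrom == chrom
            ]
        )
    has_motif = False
    has_peak = False
    for iv in regions:
        seq = genome[iv.chrom][iv.start : iv.end]
        if not has_motif:
            if scan_ggaa(seq, offset=iv.start, min_units=ggaa_min_units, chrom=iv.chrom):
                has_motif = True
            elif driver_pwm is not None and scan_pwm(
                seq, driver_pwm, offset=iv.start,
                pvalue_threshold=pvalue_threshold, chrom=iv.chrom,
            ):
                has_motif = True
        if not has_peak:
            idx = peak_sets.get(iv.chrom)
            if idx is not None and idx.overlaps_any(iv.start, iv.end):
                has_peak = True
        if has_motif and has_peak:
            return True
    return False


def build_edges(
    tf_set: list[str],
    pwms: dict[str, PositionWeightMatrix],
    regions_by_tf: dict[str, list[GenomicInterval]],
    genome: dict[str, str],
    pvalue_threshold: float = 1e-4,
) -> CircuitGraph:
    """Edge A -> B iff A's motif hits inside any of B's extended regions."""
    missing = [tf for tf in tf_set if tf not in pwms]
    if missing:
        raise ValueError(f"TF(s) without a PWM: {', '.join(sorted(missing))}")
    edges: dict[tuple[str, str], list[MotifHit]] = {}
    for target in tf_set:
        for iv in regions_by_tf[target]:
            seq = genome[iv.chrom][iv.start : iv.end]
            for source in tf_set:
                hits = scan_pwm(
                    seq,
                    pwms[source],
                    offset=iv.start,
                    pvalue_threshold=pvalue_threshold,
                    chrom=iv.chrom,
                )
                if hits:
                    edges.setdefault((source, target), []).extend(hits)
    auto = {tf for tf in tf_set if (tf, tf) in edges}
    return CircuitGraph(
        nodes=list(tf_set),
        regions={tf: list(regions_by_tf[tf]) for tf in tf_set},
        edges=edges,
        auto=auto,
    )


def enumerate_circuits(graph: CircuitGraph) -> list[Circuit]:
    """All maximal fully interconnected auto-regulatory loops.

    Nodes are restricted to auto (self-edged) TFs passing the driver
    constraint; the support graph links A and B when both A->B and B->A
    exist; maximal cliques (including size-1 singletons) are the circuits,
    ordered by size desc, evidence desc, then members lexicographically.
    """
    eligible = sorted(graph.auto & graph.driver_ok)
    support = nx.Graph()
    support.add_nodes_from(eligible)
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            if (a, b) in graph.edges and (b, a) in graph.edges:
                support.add_edge(a, b)
    circuits = []
    for clique in nx.find_cliques(support):
        members = frozenset(clique)
        evidence = sum(
            len(graph.edges.get((a, b), []))
            for a in members
            for b in members
        )
        circuits.append(Circuit(members, len(members), evidence))
    circuits.sort(key=lambda c: (-c.size, -c.total_evidence, sorted(c.members)))
    return circuits


def candidate_table(
    circuits: list[Circuit], graph: CircuitGraph, min_size: int = 2
) -> "pd.DataFrame":
    """One row per TF appearing in any circuit of size >= min_size."""
    import pandas as pd

    members: dict[str, None] = {}
    for c in circuits:
        if c.size >= min_size:
            for m in sorted(c.members):
                members.setdefault(m, None)
    rows = []
    for tf in members:
        sizes = [c.size for c in circuits if tf in c.members and c.size >= min_size]
        rows.append(
            {
                "tf": tf,
                "auto": tf in graph.auto,
                "driver_ok": tf in graph.driver_ok,
                "max_circuit_size": max(sizes),
                "out_evidence": sum(
                    len(h) for (a, _), h in graph.edges.items() if a == tf
                ),
                "in_evidence": sum(
                    len(h) for (_, b), h in graph.edges.items() if b == tf
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["tf", "auto", "driver_ok", "max_circuit_size",
                       "out_evidence", "in_evidence"]
    )
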