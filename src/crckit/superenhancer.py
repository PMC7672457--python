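"""ROSE-style super-enhancer calling.

Enhancer peaks are stitched when their gap is at most the stitch distance
(12.5 kb by default), after excluding peaks that lie fully inside a TSS
exclusion window (+-2.5 kb by default). Stitched regions are ranked by
background-subtracted signal area and separated from typical enhancers at the
hockey-stick point of the unit-scaled rank-vs-signal curve (where a slope-1
line is tangent). Each super-enhancer is assigned every gene whose TSS lies
within the assignment window (50 kb by default) -- one region may serve
several genes, which is essential when enumerating TF circuitries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import GeneAnnotation, GenomicInterval, Peak, SignalTrack


@dataclass(frozen=True)
class StitchedRegion:
    interval: GenomicInterval
    constituent_ids: tuple[str, ...]
    total_signal: float = 0.0


@dataclass(frozen=True)
class SuperEnhancer:
    region: StitchedRegion
    rank: int
    is_super: bool = False
    assigned_genes: tuple[str, ...] = ()

    @property
    def interval(self) -> GenomicInterval:
        return self.region.interval

    @property
    def total_signal(self) -> float:
        return self.region.total_signal


def stitch_peaks(
    peaks: list[Peak],
    stitch_bp: int,
    tss_list: list[tuple[str, int]] | None = None,
    tss_exclusion_bp: int = 0,
) -> list[StitchedRegion]:
    """Transitively merge peaks whose gap <= stitch_bp, per chromosome.

    Peaks fully inside any TSS +- tss_exclusion_bp window are excluded
    before stitching (containment: start >= tss - x and end <= tss + x).
    """
    if stitch_bp <= 0:
        raise ValueError("stitch_bp must be > 0")
    tss_by_chrom: dict[str, np.ndarray] = {}
    if tss_list:
        grouped: dict[str, list[int]] = {}
        for chrom, tss in tss_list:
            grouped.setdefault(chrom, []).append(tss)
        tss_by_chrom = {c: np.array(sorted(v)) for c, v in grouped.items()}

    def excluded(p: Peak) -> bool:
        tss = tss_by_chrom.get(p.interval.chrom)
        if tss is None or tss_exclusion_bp <= 0:
            return False
        # a window centered at t contains the peak iff
        # start + x >= t >= end - x  for window half-width x
        lo = p.interval.end - tss_exclusion_bp
        hi = p.interval.start + tss_exclusion_bp
        if lo > hi:
            return False
        i = np.searchsorted(tss, lo, side="left")
        return bool(i < len(tss) and tss[i] <= hi)

    kept = [p for p in peaks if not excluded(p)]
    kept.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    regions: list[StitchedRegion] = []
    cur: list[Peak] = []

    def flush() -> None:
        if not cur:
            return
        interval = GenomicInterval(
            cur[0].interval.chrom,
            cur[0].interval.start,
            max(p.interval.end for p in cur),
        )
        regions.append(
            StitchedRegion(interval, tuple(p.name for p in cur))
        )

    for p in kept:
        if (
            cur
            and p.interval.chrom == cur[-1].interval.chrom
            and p.interval.start - max(q.interval.end for q in cur) <= stitch_bp
        ):
            cur.append(p)
        else:
            flush()
            cur = [p]
    flush()
    return regions


def rank_by_signal(
    regions: list[StitchedRegion],
    track: SignalTrack,
    control: SignalTrack | None = None,
) -> list[SuperEnhancer]:
    """total_signal = sum over region bases of max(track - control, 0);
    ranks descend by signal, ties broken by (chrom, start)."""
    scored = []
    for r in regions:
        iv = r.interval
        if control is None:
            total = track.region_sum(iv.chrom, iv.start, iv.end)
        else:
            total = _clipped_difference_sum(track, control, iv)
        scored.append(replace(r, total_signal=total))
    order = sorted(
        range(len(scored)),
        key=lambda i: (
            -scored[i].total_signal,
            scored[i].interval.chrom,
            scored[i].interval.start,
        ),
    )
    ses = [None] * len(scored)
    for rank0, i in enumerate(order):
        ses[i] = SuperEnhancer(scored[i], rank=rank0 + 1)
    return list(ses)


def _clipped_difference_sum(
    track: SignalTrack, control: SignalTrack, iv: GenomicInterval
) -> float:
    """Per-base sum of max(track - control, 0) via merged breakpoints."""
    ts, te, tv = track.segments(iv.chrom)
    cs, ce, cv = control.segments(iv.chrom)
    points = np.unique(
        np.concatenate(
            [[iv.start, iv.end], ts, te, cs, ce]
        )
    )
    points = points[(points >= iv.start) & (points <= iv.end)]
    if len(points) < 2:
        return 0.0
    mids = points[:-1]
    t_vals = track.values_at(iv.chrom, mids)
    c_vals = control.values_at(iv.chrom, mids)
    widths = np.diff(points)
    return float(np.sum(np.maximum(t_vals - c_vals, 0.0) * widths))


def hockey_stick_cutoff(signals: list[float]) -> tuple[float, int]:
    """Cutoff separating super-enhancers on the unit-scaled rank curve.

    Signals are sorted ascending; rank and signal are rescaled to [0, 1];
    the cutoff sits where the gap below the diagonal (x - y) is maximal,
    i.e. where a slope-1 line is tangent to the hockey stick. Regions with
    signal strictly above the cutoff signal are super. A flat curve has no
    super-enhancers.
    """
    if len(signals) < 2:
        raise ValueError("hockey_stick_cutoff requires >= 2 regions")
    s = np.sort(np.asarray(signals, dtype=float))
    if s[0] == s[-1]:
        return float(s[-1]), 0
    n = len(s)
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    i_star = int(np.argmax(x - y))
    cutoff = float(s[i_star])
    n_super = int(np.sum(np.asarray(signals) > cutoff))
    return cutoff, n_super


def call_super_enhancers(
    ses: list[SuperEnhancer],
) -> tuple[list[SuperEnhancer], float]:
    """Flag is_super on ranked regions using the hockey-stick cutoff."""
    cutoff, _ = hockey_stick_cutoff([se.total_signal for se in ses])
    return (
        [replace(se, is_super=se.total_signal > cutoff) for se in ses],
        cutoff,
    )


def assign_to_genes(
    ses: list[SuperEnhancer],
    genes: list[GeneAnnotation],
    window_bp: int,
    nearest_only: bool = False,
) -> list[SuperEnhancer]:
    """Assign every gene whose TSS is within window_bp of the region
    (distance 0 for a TSS inside). ``nearest_only`` restricts each region
    to its single closest TSS."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    out = []
    for se in ses:
        candidates = [
            (se.interval.distance_to(g.tss), g.gene_id)
            for g in genes
            if g.chrom == se.interval.chrom
            and se.interval.distance_to(g.tss) <= window_bp
        ]
        candidates.sort()
        if nearest_only and candidates:
            candidates = candidates[:1]
        out.append(replace(se, assigned_genes=tuple(g for _, g in candidates)))
    return out


def se_assigned_tfs(
    ses: list[SuperEnhancer], genes: list[GeneAnnotation]
) -> list[str]:
    """Distinct TF gene ids with >= 1 assigned super region."""
    tf_ids = {g.gene_id for g in genes if g.is_tf}
    found: dict[str, None] = {}
    for se in ses:
        if not se.is_super:
            continue
        for gid in se.assigned_genes:
            if gid in tf_ids:
                found.setdefault(gid, None)
    return sorted(found)
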