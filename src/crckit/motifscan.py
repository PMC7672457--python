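"""PWM scanning with exact p-values, GGAA-microsatellite detection and
motif-spacing statistics.

Scores are log2 likelihood ratios (bits) of pseudocounted motif probabilities
against a 0-order background, discretized on a 1e-3-bit grid. P-values are the
exact tail probability of the discretized score distribution, computed by
dynamic programming over motif positions (the FIMO definition: probability of
an equal-or-better score for a random background word). The same discretized
score is used for hit calling, so scan results and p-values are mutually
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GenomicInterval, PositionWeightMatrix

GRANULARITY_BITS = 1e-3
DEFAULT_PSEUDOCOUNT = 1e-3

_BASES = "ACGT"


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float  # bits
    pvalue: float

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")


@dataclass(frozen=True)
class GGAARun:
    """A maximal run of consecutive GGAA tetramers (TTCC on the minus
    strand, reported as GGAA on -)."""

    interval: GenomicInterval
    strand: str
    units: int

    def __post_init__(self) -> None:
        if self.units < 1:
            raise ValueError("units must be >= 1")
        if self.interval.length != 4 * self.units:
            raise ValueError("interval length must be 4 x units")


class _ScoreModel:
    """Integer score matrix plus the exact background score distribution."""

    def __init__(self, pwm: PositionWeightMatrix, pseudocount: float):
        probs = pwm.probs + pseudocount
        probs = probs / probs.sum(axis=1, keepdims=True)
        bits = np.log2(probs / pwm.background[None, :])
        self.int_scores = np.rint(bits / GRANULARITY_BITS).astype(np.int64)
        # ambiguity codes (N etc.) score 0 bits at every position
        self.int_scores_ext = np.hstack(
            [self.int_scores, np.zeros((pwm.width, 1), dtype=np.int64)]
        )
        self.width = pwm.width
        # DP: exact distribution of the window score for a background word,
        # built by convolving the 4-point per-position distributions
        cur = np.array([1.0])
        cur_min = 0
        for i in range(pwm.width):
            row = self.int_scores[i]
            new_min = cur_min + int(row.min())
            new_len = len(cur) + int(row.max() - row.min())
            new = np.zeros(new_len)
            for b in range(4):
                shift = int(row[b]) - int(row.min())
                new[shift : shift + len(cur)] += pwm.background[b] * cur
            cur, cur_min = new, new_min
        support = np.nonzero(cur > 0)[0]
        self.scores = support + cur_min  # ascending achievable int scores
        probs_sup = cur[support]
        tail = np.cumsum(probs_sup[::-1])[::-1]
        self.tail = tail  # P(X >= scores[i])

    def pvalue_of_int(self, s: int | np.ndarray) -> np.ndarray:
        """P(window score >= s) for integer grid scores (vectorized)."""
        idx = np.searchsorted(self.scores, np.atleast_1d(s), side="left")
        out = np.where(idx < len(self.scores), self.tail[np.minimum(idx, len(self.scores) - 1)], 0.0)
        return out

    def min_hit_score(self, pvalue_threshold: float) -> int | None:
        """Smallest achievable int score with tail <= threshold."""
        ok = np.nonzero(self.tail <= pvalue_threshold)[0]
        if len(ok) == 0:
            return None
        return int(self.scores[ok[0]])


_MODEL_CACHE: dict[tuple, _ScoreModel] = {}


def _model(pwm: PositionWeightMatrix, pseudocount: float) -> _ScoreModel:
    key = (
        pwm.motif_id,
        pwm.probs.tobytes(),
        pwm.background.tobytes(),
        pseudocount,
    )
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = _ScoreModel(pwm, pseudocount)
    return _MODEL_CACHE[key]


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(idx: np.ndarray, model: _ScoreModel) -> np.ndarray:
    n = len(idx) - model.width + 1
    total = np.zeros(n, dtype=np.int64)
    for i in range(model.width):
        total += model.int_scores_ext[i, idx[i : i + n]]
    return total


def pwm_pvalue(
    pwm: PositionWeightMatrix,
    score: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Exact tail probability P(background window score >= score)."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    model = _model(pwm, pseudocount)
    s_int = int(np.ceil(score / GRANULARITY_BITS - 1e-6))
    return float(model.pvalue_of_int(s_int)[0])


def scan_pwm(
    seq: str,
    pwm: PositionWeightMatrix,
    offset: int = 0,
    pvalue_threshold: float = 1e-4,
    chrom: str = "seq",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[MotifHit]:
    """Scan both strands; a hit is reported iff its p-value <= threshold.

    A minus-strand hit at [j, j+w) means the reverse complement of the
    forward window matches the motif. Hits are sorted by start, + before -.
    """
    if len(seq) < pwm.width:
        return []
    idx = _encode(seq)
    hits: list[MotifHit] = []
    for strand, strand_pwm in (("+", pwm), ("-", pwm.reverse_complement())):
        model = _model(strand_pwm, pseudocount)
        scores = _window_scores(idx, model)
        pvals = model.pvalue_of_int(scores)
        for j in np.nonzero(pvals <= pvalue_threshold)[0]:
            hits.append(
                MotifHit(
                    pwm.motif_id,
                    GenomicInterval(
                        chrom, offset + int(j), offset + int(j) + pwm.width
                    ),
                    strand,
                    float(scores[j]) * GRANULARITY_BITS,
                    float(pvals[j]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def scan_ggaa(
    seq: str, offset: int = 0, min_units: int = 1, chrom: str = "seq"
) -> list[GGAARun]:
    """Maximal non-extendable runs of consecutive GGAA (+) / TTCC (-)."""
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    seq = seq.upper()
    runs: list[GGAARun] = []
    for strand, unit in (("+", "GGAA"), ("-", "TTCC")):
        i = 0
        n = len(seq)
        while i <= n - 4:
            if seq.startswith(unit, i):
                j = i + 4
                while seq.startswith(unit, j):
                    j += 4
                units = (j - i) // 4
                if units >= min_units:
                    runs.append(
                        GGAARun(
                            GenomicInterval(chrom, offset + i, offset + j),
                            strand,
                            units,
                        )
                    )
                i = j
            else:
                i += 1
    runs.sort(key=lambda r: (r.interval.start, r.strand))
    return runs


def spacing_stats(hits: list[MotifHit]) -> tuple[float, int, int]:
    """Nearest-neighbor edge-to-edge gaps between hits of distinct motifs.

    Each hit is paired with its closest hit of a different motif id; the
    gap is max(0, later.start - earlier.end). Returns (mean, min, max).
    """
    ids = {h.motif_id for h in hits}
    if len(ids) < 2:
        raise ValueError("spacing_stats requires hits from >= 2 motif ids")
    gaps = []
    for h in hits:
        best = None
        for other in hits:
            if other.motif_id == h.motif_id:
                continue
            first, second = sorted(
                (h, other), key=lambda x: (x.interval.start, x.interval.end)
            )
            gap = max(0, second.interval.start - first.interval.end)
            if best is None or gap < best:
                best = gap
        gaps.append(best)
    return float(np.mean(gaps)), int(min(gaps)), int(max(gaps))
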