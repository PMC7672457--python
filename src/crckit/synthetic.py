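"""Self-consistent synthetic dataset with a planted core regulatory circuit.

The generator emulates the statistical structure the analysis assumes: a toy
genome with TSS-annotated genes; H3K27ac peaks forming a heavy-tailed signal
distribution whose top stitched regions are the planted super-enhancers;
planted PWM motif instances and GGAA microsatellite runs inside designated
SEs; driver and TF ChIP peaks centered on the planted elements; a
lineage-labeled expression matrix in which the planted circuit TFs are
lineage-restricted and mutually correlated; and three knockdown DE tables
sharing a controlled downregulated core.

Ground truth is exact, not probabilistic: planted motifs use near-consensus
PWMs sharp enough that, at the FIMO threshold, a hit occurs iff the window
equals the consensus (or its reverse complement), and every off-plan
occurrence of any consensus word -- and every GGAA/TTCC run long enough to
qualify as a driver element -- is scrubbed out of the background sequence.
The emitted files alone therefore determine every planted constraint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PositionWeightMatrix,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_de_table,
    write_expression_tsv,
    write_fasta,
    write_gene_table,
    write_meme_motifs,
    DifferentialTable,
    ExpressionMatrix,
)

# geometry constants (bp); mirror the pipeline's ROSE-style defaults
CONSTITUENT_BP = 3000
CONSTITUENT_PITCH = 4000
SE1_OFFSET = 6000
SE_GAP = 13000          # > 12.5 kb stitch distance: regions stay separate
TSS_OFFSET = 1000
ASSIGN_WINDOW = 50000   # SE-to-gene assignment window the pipeline uses
TSS_SPACING = 4000      # 2 x promoter window
SCRUB_GGAA_UNITS = 4    # runs >= this many units qualify as driver elements
PROMOTER_K27AC_HALF = 1000
PROMOTER_K4ME3_HALF = 250
TF_PEAK_HALF = 150

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticDatasetConfig:
    n_chroms: int = 2
    chrom_len_bp: int = 500_000
    n_genes: int = 200
    n_tfs: int = 30
    planted_circuit: list[str] = field(
        default_factory=lambda: ["TFC1", "TFC2", "TFC3"]
    )
    decoy_tfs_no_auto: int = 3
    decoy_tfs_no_driver: int = 3
    motif_width: int = 8
    n_se: int = 20
    se_span_bp: int = 20_000
    typical_enhancer_bp: int = 1000
    signal_noise_sd: float = 0.1
    driver_motif: int = 6  # GGAA units planted per driver element
    expr_lineages: int = 5
    samples_per_lineage: int = 4
    shared_down_fraction: float = 0.5
    de_set_size: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.motif_width < 7:
            raise ConfigError(
                "motif_width must be >= 7 so that consensus hits are the "
                "only hits at the FIMO threshold"
            )
        if not (0 <= self.shared_down_fraction <= 1):
            raise ConfigError("shared_down_fraction must be in [0, 1]")
        for key in ("n_chroms", "chrom_len_bp", "n_genes", "n_tfs", "n_se",
                    "se_span_bp", "typical_enhancer_bp", "expr_lineages",
                    "samples_per_lineage", "de_set_size"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")
        n_special = (
            len(self.planted_circuit)
            + self.decoy_tfs_no_auto
            + self.decoy_tfs_no_driver
        )
        if n_special > self.n_tfs:
            raise ConfigError("more special TFs than n_tfs")
        if n_special > self.n_se:
            raise ConfigError("more special TFs than super-enhancers")
        if self.n_tfs > self.n_genes:
            raise ConfigError("more TFs than genes")
        if self.driver_motif < SCRUB_GGAA_UNITS:
            raise ConfigError(
                f"driver_motif must be >= {SCRUB_GGAA_UNITS} units"
            )


@dataclass
class TruthRecord:
    """Every planted coordinate and set, checkable from the emitted files."""

    circuit: list[str]
    decoys_no_auto: list[str]
    decoys_no_driver: list[str]
    filler_tfs: list[str]
    se_assigned_tfs: list[str]
    se_intervals: dict[str, list]            # tf -> [chrom, start, end]
    empty_se_intervals: list[list]
    motif_instances: list[list]              # [motif_id, chrom, start, end, strand]
    ggaa_runs: list[list]                    # [chrom, start, end, units]
    driver_peaks: list[list]
    adjacency: list[list]                    # [source_tf, target_tf]
    de_down: dict[str, list]
    de_core: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


def truth_report(truth: TruthRecord) -> pd.DataFrame:
    """Machine-readable ground-truth table: one row per TF."""
    rows = []
    roles = (
        [(tf, "circuit", 1, "") for tf in truth.circuit]
        + [(tf, "decoy_no_auto", 0, "no_auto_motif") for tf in truth.decoys_no_auto]
        + [
            (tf, "decoy_no_driver", 0, "no_driver_evidence")
            for tf in truth.decoys_no_driver
        ]
        + [(tf, "other_tf", 0, "no_super_enhancer") for tf in truth.filler_tfs]
    )
    for tf, role, in_circuit, violated in roles:
        iv = truth.se_intervals.get(tf)
        rows.append(
            {
                "tf": tf,
                "role": role,
                "circuit": in_circuit,
                "violated_constraint": violated,
                "se_chrom": iv[0] if iv else "",
                "se_start": iv[1] if iv else -1,
                "se_end": iv[2] if iv else -1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    chrom_names: list[str]
    chrom_len: int
    unit_len: int
    n_units: int
    special_slots: list[tuple[str, int]]   # (chrom, unit start) for SE1+TSS
    empty_se_starts: list[tuple[str, int]]
    typical_starts: list[tuple[str, int]]
    filler_slots: list[tuple[str, int]]    # candidate filler-TF TSSs
    se_span: int
    n_constituents: int


def _plan_layout(cfg: SyntheticDatasetConfig) -> _Layout:
    n_const = max(1, (cfg.se_span_bp - CONSTITUENT_BP) // CONSTITUENT_PITCH + 1)
    span = (n_const - 1) * CONSTITUENT_PITCH + CONSTITUENT_BP
    # next unit's special TSS must sit > ASSIGN_WINDOW past this unit's SE
    unit_len = ASSIGN_WINDOW + SE1_OFFSET + span + 1000 - TSS_OFFSET
    n_units = cfg.chrom_len_bp // unit_len
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_special = (
        len(cfg.planted_circuit) + cfg.decoy_tfs_no_auto + cfg.decoy_tfs_no_driver
    )
    slots = [(c, u * unit_len) for c in chroms for u in range(n_units)]
    if n_special > len(slots):
        raise ConfigError(
            f"geometry infeasible: {n_special} special TFs need SE units but "
            f"only {len(slots)} fit on the genome"
        )
    # order slots chromosome-major so the circuit occupies the first units
    special_slots = slots[:n_special]
    spare_se1 = slots[n_special:]
    se2_off = SE1_OFFSET + span + SE_GAP
    # SE2 slots in all but the last unit per chromosome keep the chromosome
    # tail >= 50 kb clear of super-enhancers for the filler TFs
    se2_slots = [
        (c, u * unit_len + se2_off)
        for c in chroms
        for u in range(n_units - 1)
    ]
    n_empty = cfg.n_se - n_special
    if n_empty < 0:
        raise ConfigError("n_se smaller than the number of special TFs")
    empty_pool = [(c, u + SE1_OFFSET) for c, u in spare_se1] + se2_slots
    if n_empty > len(empty_pool):
        raise ConfigError(
            f"geometry infeasible: need {n_empty} decoy SE slots, have "
            f"{len(empty_pool)}"
        )
    empty_se_starts = empty_pool[:n_empty]
    # typical enhancers in the back half of the last unit per chromosome
    typical_starts = []
    last_u = (n_units - 1) * unit_len
    t = last_u + SE1_OFFSET + span + SE_GAP
    while t + cfg.typical_enhancer_bp + SE_GAP <= last_u + unit_len:
        for c in chroms:
            typical_starts.append((c, t))
        t += cfg.typical_enhancer_bp + SE_GAP
    typical_starts.sort()
    # filler-TF zone: tail, > assignment window past the last SE
    per_chrom_max: dict[str, int] = {}
    for c, u in special_slots:
        per_chrom_max[c] = max(per_chrom_max.get(c, 0), u + SE1_OFFSET + span)
    for c, s in empty_se_starts:
        per_chrom_max[c] = max(per_chrom_max.get(c, 0), s + span)
    filler_slots = []
    for c in chroms:
        zone = per_chrom_max.get(c, 0) + ASSIGN_WINDOW + 1500
        pos = zone
        while pos + 500 <= cfg.chrom_len_bp:
            filler_slots.append((c, pos))
            pos += TSS_SPACING
    n_filler = cfg.n_tfs - n_special
    if n_filler > len(filler_slots):
        raise ConfigError(
            f"geometry infeasible: need {n_filler} filler-TF slots, have "
            f"{len(filler_slots)}"
        )
    return _Layout(
        chroms, cfg.chrom_len_bp, unit_len, n_units, special_slots,
        empty_se_starts, typical_starts, filler_slots, span, n_const,
    )


def _merge_forbidden(zones: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not zones:
        return []
    zones = sorted(zones)
    out = [list(zones[0])]
    for s, e in zones[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _place_gene_tsss(
    chrom_len: int,
    forbidden: list[tuple[int, int]],
    existing: list[int],
    needed_max: int,
) -> list[int]:
    """Greedy left-to-right TSS placement at >= TSS_SPACING from existing
    TSSs and outside forbidden zones (inclusive)."""
    zones = list(forbidden)
    for t in existing:
        zones.append((t - TSS_SPACING + 1, t + TSS_SPACING - 1))
    zones = _merge_forbidden(zones)
    placed: list[int] = []
    pos = 500
    zi = 0
    while pos + 500 <= chrom_len and len(placed) < needed_max:
        while zi < len(zones) and zones[zi][1] < pos:
            zi += 1
        if zi < len(zones) and zones[zi][0] <= pos <= zones[zi][1]:
            pos = zones[zi][1] + 1
            continue
        placed.append(pos)
        pos += TSS_SPACING
    return placed


# ---------------------------------------------------------------------------
# motif words and scrubbing
# ---------------------------------------------------------------------------

def _ggaa_family(width: int) -> set[str]:
    tandem = "GGAA" * (width // 4 + 2)
    ttcc = "TTCC" * (width // 4 + 2)
    out = set()
    for i in range(4):
        out.add(tandem[i : i + width])
        out.add(ttcc[i : i + width])
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _choose_motif_words(rng: np.random.Generator, n: int, width: int) -> list[str]:
    """Random consensus words, pairwise Hamming >= 3 (including reverse
    complements), excluding GGAA-microsatellite phases."""
    banned = _ggaa_family(width)
    words: list[str] = []
    guard = 0
    while len(words) < n:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("could not choose distinct motif words")
        w = "".join(rng.choice(list("ACGT"), size=width))
        if w in banned or _revcomp(w) in banned:
            continue
        if _hamming(w, _revcomp(w)) < 3:
            continue
        ok = True
        for prev in words:
            for q in (prev, _revcomp(prev)):
                if _hamming(w, q) < 3:
                    ok = False
        if ok:
            words.append(w)
    return words


def _scrub_background(
    genome: dict[str, bytearray],
    patterns: dict[bytes, str],           # pattern -> motif id ("" for GGAA)
    planted_motifs: dict[tuple[str, int], str],
    ggaa_spans: list[tuple[str, int, int]],
    protected: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> None:
    """Mutate background bases until no off-plan pattern occurrence remains."""
    bases = b"ACGT"
    for _ in range(50):
        dirty = 0
        for chrom, seq in genome.items():
            for pat, motif_id in patterns.items():
                start = 0
                while True:
                    i = seq.find(pat, start)
                    if i < 0:
                        break
                    start = i + 1
                    if motif_id:
                        if planted_motifs.get((chrom, i)) == motif_id:
                            continue
                    else:
                        if any(
                            c == chrom and s <= i and i + len(pat) <= e
                            for c, s, e in ggaa_spans
                        ):
                            continue
                    free = [
                        j
                        for j in range(i, i + len(pat))
                        if not protected[chrom][j]
                    ]
                    if not free:
                        raise RuntimeError(
                            "unscrubbable occurrence inside planted features"
                        )
                    j = free[len(free) // 2]
                    cur = seq[j]
                    choices = [b for b in bases if b != cur]
                    seq[j] = choices[int(rng.integers(len(choices)))]
                    dirty += 1
        if dirty == 0:
            return
    raise RuntimeError("scrubbing did not converge")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_dataset(
    cfg: SyntheticDatasetConfig, out_dir: str | Path
) -> tuple[dict[str, Path], TruthRecord]:
    """Write the full file bundle; return (paths, ground truth)."""
    return _generate(cfg, out_dir, planted=True)


def generate_null_dataset(
    cfg: SyntheticDatasetConfig, out_dir: str | Path
) -> dict[str, Path]:
    """As generate_dataset but with motif/driver placements randomized
    genome-wide and no planted expression or DE structure."""
    paths, _ = _generate(cfg, out_dir, planted=False)
    return paths


def _generate(
    cfg: SyntheticDatasetConfig, out_dir: str | Path, planted: bool
) -> tuple[dict[str, Path], TruthRecord]:
    cfg.validate()
    layout = _plan_layout(cfg)
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    circuit = list(cfg.planted_circuit)
    no_auto = [f"TFNA{i + 1}" for i in range(cfg.decoy_tfs_no_auto)]
    no_driver = [f"TFND{i + 1}" for i in range(cfg.decoy_tfs_no_driver)]
    specials = circuit + no_auto + no_driver
    n_filler = cfg.n_tfs - len(specials)
    fillers = [f"TFX{i + 1:02d}" for i in range(n_filler)]

    # genome background
    genome: dict[str, bytearray] = {}
    for chrom in layout.chrom_names:
        idx = rng.integers(0, 4, size=cfg.chrom_len_bp)
        genome[chrom] = bytearray(bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[idx]))
    protected = {
        chrom: np.zeros(cfg.chrom_len_bp, dtype=bool)
        for chrom in layout.chrom_names
    }

    # motif consensus words and PWMs for every TF
    words = _choose_motif_words(rng, cfg.n_tfs, cfg.motif_width)
    tf_order = specials + fillers
    word_of = dict(zip(tf_order, words))
    pwms = []
    for tf in tf_order:
        probs = np.full((cfg.motif_width, 4), 0.01)
        for i, base in enumerate(word_of[tf]):
            probs[i, "ACGT".index(base)] = 0.97
        pwms.append(PositionWeightMatrix(tf, probs))

    # planted features
    se_of: dict[str, tuple[str, int, int]] = {}
    for tf, (chrom, u) in zip(specials, layout.special_slots):
        s = u + SE1_OFFSET
        se_of[tf] = (chrom, s, s + layout.se_span)
    empty_ses = [
        (chrom, s, s + layout.se_span) for chrom, s in layout.empty_se_starts
    ]

    planted_motifs: dict[tuple[str, int], str] = {}
    motif_instances: list[list] = []
    ggaa_spans: list[tuple[str, int, int]] = []
    ggaa_rows: list[list] = []
    driver_peaks: list[list] = []
    factor_peaks: dict[str, list[list]] = {tf: [] for tf in circuit}

    def plant_word(chrom: str, pos: int, tf: str) -> None:
        word = word_of[tf]
        strand = "+" if rng.integers(2) == 0 else "-"
        written = word if strand == "+" else _revcomp(word)
        genome[chrom][pos : pos + cfg.motif_width] = written.encode()
        protected[chrom][pos : pos + cfg.motif_width] = True
        planted_motifs[(chrom, pos)] = tf
        motif_instances.append([tf, chrom, pos, pos + cfg.motif_width, strand])

    def plant_ggaa(chrom: str, pos: int) -> None:
        run = "GGAA" * cfg.driver_motif
        genome[chrom][pos : pos + len(run)] = run.encode()
        protected[chrom][pos : pos + len(run)] = True
        ggaa_spans.append((chrom, pos, pos + len(run)))
        ggaa_rows.append([chrom, pos, pos + len(run), cfg.driver_motif])
        driver_peaks.append([chrom, pos - 138, pos + len(run) + 138])

    def plant_cluster(chrom: str, se_start: int, motif_tfs: list[str],
                      with_driver: bool, record_factor_peaks: bool) -> None:
        # planted elements sit inside the second SE constituent
        pos = se_start + CONSTITUENT_PITCH + 200
        for tf in motif_tfs:
            plant_word(chrom, pos, tf)
            if record_factor_peaks and tf in factor_peaks:
                center = pos + cfg.motif_width // 2
                factor_peaks[tf].append(
                    [chrom, center - TF_PEAK_HALF, center + TF_PEAK_HALF]
                )
            pos += cfg.motif_width + int(rng.integers(16, 32))
        if with_driver:
            plant_ggaa(chrom, pos + 20)

    if planted:
        for tf in circuit:
            chrom, s, _ = se_of[tf]
            plant_cluster(chrom, s, circuit, with_driver=True,
                          record_factor_peaks=True)
        for tf in no_auto:
            chrom, s, _ = se_of[tf]
            plant_cluster(chrom, s, circuit, with_driver=True,
                          record_factor_peaks=True)
        for tf in no_driver:
            chrom, s, _ = se_of[tf]
            plant_cluster(chrom, s, [tf], with_driver=False,
                          record_factor_peaks=False)
    else:
        # same feature multiset, positions uniform over the genome
        counts: dict[str, int] = {}
        for tf in circuit:
            counts[tf] = len(circuit) + len(no_auto)
        for tf in no_driver:
            counts[tf] = 1
        n_runs = len(circuit) + len(no_auto)
        for tf, count in counts.items():
            for _ in range(count):
                for _attempt in range(1000):
                    chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
                    pos = int(rng.integers(0, cfg.chrom_len_bp - cfg.motif_width))
                    if not protected[chrom][pos : pos + cfg.motif_width].any():
                        break
                plant_word(chrom, pos, tf)
                if tf in factor_peaks:
                    center = pos + cfg.motif_width // 2
                    factor_peaks[tf].append(
                        [chrom, center - TF_PEAK_HALF, center + TF_PEAK_HALF]
                    )
        run_len = 4 * cfg.driver_motif
        for _ in range(n_runs):
            for _attempt in range(1000):
                chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
                pos = int(rng.integers(138, cfg.chrom_len_bp - run_len - 138))
                if not protected[chrom][pos : pos + run_len].any():
                    break
            plant_ggaa(chrom, pos)

    # scrub every off-plan occurrence of any consensus word or GGAA run
    patterns: dict[bytes, str] = {}
    for tf in tf_order:
        w = word_of[tf]
        patterns[w.encode()] = tf
        if _revcomp(w) != w:
            patterns[_revcomp(w).encode()] = tf
    patterns[("GGAA" * SCRUB_GGAA_UNITS).encode()] = ""
    patterns[("TTCC" * SCRUB_GGAA_UNITS).encode()] = ""
    _scrub_background(
        genome, patterns, planted_motifs, ggaa_spans, protected, rng
    )

    # ---------------- gene placement ----------------
    special_tss = {
        tf: (chrom, u + TSS_OFFSET)
        for tf, (chrom, u) in zip(specials, layout.special_slots)
    }
    filler_tss = {
        tf: slot for tf, slot in zip(fillers, layout.filler_slots)
    }
    constituents: list[tuple[str, int, int]] = []
    for chrom, s, e in list(se_of.values()) + empty_ses:
        for i in range(layout.n_constituents):
            c = s + i * CONSTITUENT_PITCH
            constituents.append((chrom, c, c + CONSTITUENT_BP))
    typicals = [
        (chrom, t, t + cfg.typical_enhancer_bp)
        for chrom, t in layout.typical_starts
    ]

    n_non_tf = cfg.n_genes - cfg.n_tfs
    non_tf_positions: list[tuple[str, int]] = []
    for chrom in layout.chrom_names:
        forbidden = []
        for c, s, e in constituents:
            if c == chrom:
                # keep promoter H3K4me3 peaks clear of enhancer constituents
                forbidden.append((s - PROMOTER_K4ME3_HALF, e + PROMOTER_K4ME3_HALF))
        for c, s, e in typicals:
            if c == chrom:
                forbidden.append((s - 1500, s + 2500))
        # keep the planted-cluster constituent free of promoter marks
        for tf in specials:
            c, s, _ = se_of[tf]
            if c == chrom:
                c1 = s + CONSTITUENT_PITCH
                forbidden.append((c1 - 500, c1 + CONSTITUENT_BP + 500))
        existing = [t for c, t in special_tss.values() if c == chrom]
        existing += [t for c, t in filler_tss.values() if c == chrom]
        remaining = n_non_tf - len(non_tf_positions)
        for pos in _place_gene_tsss(
            cfg.chrom_len_bp, forbidden, existing, remaining
        ):
            non_tf_positions.append((chrom, pos))
    if len(non_tf_positions) < n_non_tf:
        raise ConfigError(
            f"geometry infeasible: placed {len(non_tf_positions)} of "
            f"{n_non_tf} non-TF genes"
        )

    genes: list[GeneAnnotation] = []
    for tf in specials:
        chrom, tss = special_tss[tf]
        genes.append(GeneAnnotation(tf, tf, chrom, "+", tss, True))
    for tf in fillers:
        chrom, tss = filler_tss[tf]
        genes.append(GeneAnnotation(tf, tf, chrom, "+", tss, True))
    for i, (chrom, tss) in enumerate(non_tf_positions):
        strand = "+" if rng.integers(2) == 0 else "-"
        gid = f"G{i + 1:03d}"
        genes.append(GeneAnnotation(gid, gid, chrom, strand, tss, False))
    genes.sort(key=lambda g: (g.chrom, g.tss))

    # ---------------- peaks and tracks ----------------
    def peak(chrom: str, s: int, e: int, name: str, signal: float) -> Peak:
        return Peak(GenomicInterval(chrom, s, e), name, signal)

    k27_peaks: list[Peak] = []
    me1_peaks: list[Peak] = []
    me3_peaks: list[Peak] = []
    i_pk = 0
    for chrom, s, e in constituents:
        i_pk += 1
        sig = float(rng.uniform(15, 25))
        k27_peaks.append(peak(chrom, s, e, f"k27_se_{i_pk}", sig))
        me1_peaks.append(peak(chrom, s, e, f"me1_se_{i_pk}", float(rng.uniform(5, 10))))
    for chrom, s, e in typicals:
        i_pk += 1
        k27_peaks.append(peak(chrom, s, e, f"k27_te_{i_pk}", float(rng.uniform(1, 2))))
        me1_peaks.append(peak(chrom, s, e, f"me1_te_{i_pk}", float(rng.uniform(3, 6))))
    # promoter peaks: K4me3 always; K27ac only when it would not overlap an
    # existing enhancer peak (genes inside SEs share the constituent signal)
    existing_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in k27_peaks:
        existing_by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    from .intervals import IntervalSet

    k27_idx = {c: IntervalSet(v) for c, v in existing_by_chrom.items()}
    promoter_genes: list[GeneAnnotation] = []
    for g in genes:
        me3_peaks.append(
            peak(
                g.chrom, g.tss - PROMOTER_K4ME3_HALF, g.tss + PROMOTER_K4ME3_HALF,
                f"me3_{g.gene_id}", float(rng.uniform(5, 10)),
            )
        )
        s, e = g.tss - PROMOTER_K27AC_HALF, g.tss + PROMOTER_K27AC_HALF
        if not (g.chrom in k27_idx and k27_idx[g.chrom].overlaps_any(s, e)):
            k27_peaks.append(
                peak(g.chrom, s, e, f"k27_pr_{g.gene_id}", float(rng.uniform(3, 6)))
            )
            promoter_genes.append(g)
    for plist in (k27_peaks, me1_peaks, me3_peaks):
        plist.sort(key=lambda p: (p.interval.chrom, p.interval.start))

    # combinatorial TF occupancy: cooperative (dual/trio) binding is more
    # common than solo binding at both promoters and enhancers; the fusion
    # driver binds enhancer elements only. Extra driver peaks are placed
    # only on typical enhancers, which can never enter a TF's extended
    # super-enhancer region set, so the planted driver constraint is
    # untouched.
    def draw_pattern(p_none: float, p_solo: float, p_dual: float) -> list[str]:
        r = float(rng.random())
        members = list(factor_peaks)
        if r < p_none or not members:
            return []
        if r < p_none + p_solo:
            return [members[int(rng.integers(len(members)))]]
        if r < p_none + p_solo + p_dual and len(members) >= 2:
            picked = rng.choice(len(members), size=2, replace=False)
            return [members[int(i)] for i in sorted(picked)]
        return members

    for g in promoter_genes:
        for tf in draw_pattern(0.22, 0.25, 0.32):
            factor_peaks[tf].append(
                [g.chrom, g.tss - TF_PEAK_HALF, g.tss + TF_PEAK_HALF]
            )
    cluster_constituents = {
        (c, s + CONSTITUENT_PITCH) for c, s, _ in se_of.values()
    }
    for chrom, s, e in constituents:
        if (chrom, s) in cluster_constituents:
            continue
        mid = (s + e) // 2
        for tf in draw_pattern(0.45, 0.17, 0.20):
            factor_peaks[tf].append(
                [chrom, mid - TF_PEAK_HALF, mid + TF_PEAK_HALF]
            )
    for i_t, (chrom, s, e) in enumerate(typicals):
        mid = (s + e) // 2
        pattern = draw_pattern(0.40, 0.20, 0.20)
        for tf in pattern:
            factor_peaks[tf].append(
                [chrom, mid - TF_PEAK_HALF, mid + TF_PEAK_HALF]
            )
        if pattern and len(pattern) >= 2:
            driver_peaks.append([chrom, mid - TF_PEAK_HALF, mid + TF_PEAK_HALF])

    def track_from(peaks: list[Peak]) -> SignalTrack:
        records = []
        for p in peaks:
            s, e = p.interval.start, p.interval.end
            cuts = np.linspace(s, e, 4).astype(int)
            for a, b in zip(cuts[:-1], cuts[1:]):
                if b > a:
                    v = max(0.0, p.signal + float(rng.normal(0, cfg.signal_noise_sd)))
                    records.append((p.interval.chrom, int(a), int(b), v))
        return SignalTrack.from_records(records)

    k27_track = track_from(k27_peaks)
    me1_track = track_from(me1_peaks)
    me3_track = track_from(me3_peaks)

    # ---------------- expression ----------------
    lineages = [f"lin{i}" for i in range(cfg.expr_lineages)]
    samples = [
        f"{lin}_s{j + 1}"
        for lin in lineages
        for j in range(cfg.samples_per_lineage)
    ]
    lineage_of = {s: s.split("_")[0] for s in samples}
    gene_ids = [g.gene_id for g in genes]
    base = rng.uniform(5, 50, size=len(gene_ids))
    values = base[:, None] * rng.uniform(0.8, 1.25, size=(len(gene_ids), len(samples)))
    expr_df = pd.DataFrame(values, index=gene_ids, columns=samples)
    if planted:
        shared = np.linspace(-1, 1, cfg.samples_per_lineage)
        lin0 = [s for s in samples if lineage_of[s] == lineages[0]]
        other = [s for s in samples if lineage_of[s] != lineages[0]]
        for tf in circuit:
            expr_df.loc[tf, lin0] = (
                60.0 + 30.0 * shared + rng.normal(0, 0.5, cfg.samples_per_lineage)
            )
            expr_df.loc[tf, other] = rng.uniform(0.5, 3.0, size=len(other))
    expr = ExpressionMatrix(expr_df.clip(lower=0.0).round(4), lineage_of)

    # ---------------- differential tables ----------------
    non_tf_ids = [g.gene_id for g in genes if not g.is_tf]
    core_n = int(round(cfg.shared_down_fraction * cfg.de_set_size))
    de_tables: dict[str, DifferentialTable] = {}
    de_down: dict[str, list[str]] = {}
    if planted:
        # knocking a circuit TF down reduces itself and both partners, so
        # all three TFs sit in the shared downregulated core
        core = (circuit + non_tf_ids)[:core_n]
        uniq_cursor = max(core_n - len(circuit), 0)
        for tf in circuit:
            n_uniq = cfg.de_set_size - len(core)
            uniq = non_tf_ids[uniq_cursor : uniq_cursor + n_uniq]
            uniq_cursor += n_uniq
            down = sorted(set(core + uniq))
            de_tables[tf] = _make_de_table(gene_ids, down, rng)
            de_down[tf] = down
        de_core = sorted(
            set.intersection(*(set(v) for v in de_down.values()))
        )
    else:
        for i, tf in enumerate(circuit):
            down = sorted(
                rng.choice(non_tf_ids, size=min(cfg.de_set_size, len(non_tf_ids)),
                           replace=False)
            )
            de_tables[tf] = _make_de_table(gene_ids, down, rng)
            de_down[tf] = list(down)
        de_core = sorted(
            set.intersection(*(set(v) for v in de_down.values()))
        )

    # ---------------- truth ----------------
    adjacency = []
    if planted:
        for target in circuit + no_auto:
            for source in circuit:
                adjacency.append([source, target])
        for tf in no_driver:
            adjacency.append([tf, tf])
    truth = TruthRecord(
        circuit=circuit,
        decoys_no_auto=no_auto,
        decoys_no_driver=no_driver,
        filler_tfs=fillers,
        se_assigned_tfs=sorted(specials),
        se_intervals={tf: list(se_of[tf]) for tf in specials},
        empty_se_intervals=[list(t) for t in empty_ses],
        motif_instances=motif_instances,
        ggaa_runs=ggaa_rows,
        driver_peaks=driver_peaks,
        adjacency=sorted(adjacency),
        de_down=de_down,
        de_core=de_core,
    )

    # ---------------- write bundle ----------------
    paths: dict[str, Path] = {}

    def emit(key: str, name: str) -> Path:
        paths[key] = out_dir / name
        return paths[key]

    write_fasta({c: genome[c].decode() for c in layout.chrom_names},
                emit("genome", "genome.fa"))
    write_gene_table(genes, emit("genes", "genes.tsv"))
    write_bed(k27_peaks, emit("h3k27ac_peaks", "h3k27ac_peaks.bed"))
    write_bed(me1_peaks, emit("h3k4me1_peaks", "h3k4me1_peaks.bed"))
    write_bed(me3_peaks, emit("h3k4me3_peaks", "h3k4me3_peaks.bed"))
    write_bedgraph(k27_track, emit("h3k27ac_track", "h3k27ac.bedgraph"))
    write_bedgraph(me1_track, emit("h3k4me1_track", "h3k4me1.bedgraph"))
    write_bedgraph(me3_track, emit("h3k4me3_track", "h3k4me3.bedgraph"))
    write_meme_motifs(pwms, emit("motifs", "motifs.meme"))
    driver_bed = [
        Peak(GenomicInterval(c, s, e), f"driver_{i + 1}", 10.0)
        for i, (c, s, e) in enumerate(sorted(driver_peaks))
    ]
    write_bed(driver_bed, emit("driver_peaks", "driver_peaks.bed"))
    for tf in circuit:
        rows = [
            Peak(GenomicInterval(c, s, e), f"{tf}_pk{i + 1}", 8.0)
            for i, (c, s, e) in enumerate(sorted(factor_peaks[tf]))
        ]
        write_bed(rows, emit(f"tf_peaks_{tf}", f"tf_peaks_{tf}.bed"))
    write_expression_tsv(expr, emit("expression", "expression.tsv"),
                         emit("lineages", "lineages.tsv"))
    for tf in circuit:
        write_de_table(de_tables[tf], emit(f"de_{tf}", f"de_{tf}.tsv"))
    truth.to_json(emit("truth_json", "truth.json"))
    truth_report(truth).to_csv(emit("truth", "truth.tsv"), sep="\t", index=False)
    with open(emit("config", "config.yaml"), "w") as fh:
        yaml.safe_dump(
            {**asdict(cfg), "planted": planted}, fh, sort_keys=True
        )
    return paths, truth


def _make_de_table(
    gene_ids: list[str], down: list[str], rng: np.random.Generator
) -> DifferentialTable:
    """Down genes pass padj < 0.05 and log2fc < -1 comfortably; every other
    gene fails both thresholds by a factor of >= 2."""
    down_set = set(down)
    rows = []
    for g in gene_ids:
        if g in down_set:
            lfc = -(1.1 + 1.4 * float(rng.random()))
            padj = 10.0 ** float(rng.uniform(-6, -3))
        else:
            lfc = float(rng.uniform(-0.25, 0.25))
            padj = float(rng.uniform(0.1, 0.95))
        rows.append({"gene_id": g, "log2fc": round(lfc, 4), "padj": round(padj, 6)})
    return DifferentialTable(pd.DataFrame(rows))
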