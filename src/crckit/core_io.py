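"""Domain types and readers/writers for the formats the pipeline touches.

All coordinates are 0-based half-open ([start, end)), the BED convention,
everywhere in the package; bedGraph intervals are read in the same convention.
A strict bedGraph dialect is enforced (no overlapping segments) so that signal
aggregation is unambiguous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A malformed record in an input file (message names the line)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp shared; abutting half-open intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, pos: int) -> int:
        """Distance from a point to the closed base span [start, end-1].

        0 when the point lies inside the interval.
        """
        if pos < self.start:
            return self.start - pos
        if pos > self.end - 1:
            return pos - (self.end - 1)
        return 0


@dataclass(frozen=True)
class Peak:
    """A genomic interval with a mean signal density (a.u. per bp)."""

    interval: GenomicInterval
    name: str
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak {self.name}: signal must be >= 0")


class SignalTrack:
    """Piecewise-constant, non-overlapping, sorted per-chromosome signal.

    Stored as per-chromosome (starts, ends, values) numpy arrays. Bases not
    covered by any segment have value 0.
    """

    def __init__(self, segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._segs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("ragged track arrays")
            if np.any(values < 0):
                raise ValueError(f"negative signal value on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty/inverted segment on {chrom}")
            if len(starts) > 1:
                if np.any(np.diff(starts) < 0):
                    raise ValueError(f"segments on {chrom} not sorted")
                if np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"overlapping segments on {chrom}")
            self._segs[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        segs = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.array(rows, dtype=float)
            segs[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(segs)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._segs)

    def segments(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._segs:
            empty = np.empty(0)
            return empty.astype(np.int64), empty.astype(np.int64), empty
        return self._segs[chrom]

    def iter_records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._segs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-base values at ``positions`` (0 where uncovered)."""
        starts, ends, values = self.segments(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        if len(starts) == 0:
            return np.zeros(len(positions))
        idx = np.searchsorted(starts, positions, side="right") - 1
        idx_clip = np.clip(idx, 0, len(starts) - 1)
        covered = (idx >= 0) & (positions < ends[idx_clip])
        out = np.where(covered, values[idx_clip], 0.0)
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end)."""
        starts, ends, values = self.segments(chrom)
        if len(starts) == 0:
            return 0.0
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        for chrom in self.chroms:
            for a, b in zip(self._segs[chrom], other._segs[chrom]):
                if not np.array_equal(a, b):
                    return False
        return True


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    is_tf: bool

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0")


_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Base-probability matrix over A,C,G,T with a 0-order background."""

    motif_id: str
    probs: np.ndarray  # width x 4
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: probs must be width x 4")
        if np.any(probs < 0) or np.any(bg < 0):
            raise ValueError(f"{self.motif_id}: negative probabilities")
        if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        if abs(bg.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.motif_id, self.probs[::-1, ::-1].copy(), self.background.copy()
        )

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=1))


class ExpressionMatrix:
    """TPM values per gene x sample, each sample carrying a lineage label."""

    def __init__(self, values: pd.DataFrame, lineage: Mapping[str, str]):
        if values.index.duplicated().any():
            raise ValueError("duplicated gene ids in expression matrix")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        missing = [s for s in values.columns if s not in lineage]
        if missing:
            raise ValueError(f"samples without lineage label: {missing}")
        self.values = values.astype(float)
        self.values.index.name = "gene_id"
        self.values.columns.name = None
        self.lineage = {s: lineage[s] for s in values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.lineage[s], None)
        return list(seen)

    def samples_of(self, lineage: str) -> list[str]:
        out = [s for s in self.samples if self.lineage[s] == lineage]
        if not out:
            raise KeyError(f"unknown lineage: {lineage}")
        return out


@dataclass
class DifferentialTable:
    """A DESeq2-style differential expression table (one row per gene)."""

    frame: pd.DataFrame  # columns gene_id, log2fc, padj

    def __post_init__(self) -> None:
        required = ["gene_id", "log2fc", "padj"]
        for col in required:
            if col not in self.frame.columns:
                raise ValueError(f"missing column {col}")
        if self.frame["gene_id"].duplicated().any():
            raise ValueError("duplicated gene_id in differential table")
        padj = self.frame["padj"]
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("padj outside [0, 1]")


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults follow the published procedure where the
    paper prints a value (500 bp extension, top-5 specificity, |log2FC| > 0.5,
    strict log2FC < -1, TPM floor 0.5) and ROSE/FIMO convention elsewhere."""

    se_stitch_bp: int = 12500
    tss_exclusion_bp: int = 2500
    se_extension_bp: int = 500
    se_assign_window_bp: int = 50000
    fimo_pvalue: float = 1e-4
    ggaa_min_units: int = 4
    specificity_topk: int = 5
    de_padj: float = 0.05
    de_abs_lfc: float = 0.5
    strict_lfc: float = 1.0
    tpm_min: float = 0.5
    promoter_window_bp: int = 2000
    profile_halfwidth_bp: int = 2000
    profile_bins: int = 100
    n_perm: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        errors = []
        for key in (
            "se_stitch_bp",
            "tss_exclusion_bp",
            "se_extension_bp",
            "se_assign_window_bp",
            "promoter_window_bp",
            "profile_halfwidth_bp",
        ):
            if getattr(self, key) <= 0:
                errors.append(f"{key} must be > 0")
        if not (0 < self.fimo_pvalue < 1):
            errors.append("fimo_pvalue must be in (0, 1)")
        if self.ggaa_min_units < 1:
            errors.append("ggaa_min_units must be >= 1")
        if self.specificity_topk < 1:
            errors.append("specificity_topk must be >= 1")
        if self.n_perm < 1:
            errors.append("n_perm must be >= 1")
        if self.profile_bins < 1:
            errors.append("profile_bins must be >= 1")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED5 into Peaks sorted by (chrom, start).

    Missing name -> "peak_<i>" (1-based input order); missing score -> 0.
    """
    peaks: list[Peak] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak_{lineno}"
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate peak name {name}")
            names.add(name)
            signal = 0.0
            if len(fields) > 4 and fields[4]:
                try:
                    signal = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from None
                if signal < 0:
                    raise ParseError(f"{path}:{lineno}: negative score")
            peaks.append(Peak(GenomicInterval(chrom, start, end), name, signal))
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.name}\t{p.signal:.6g}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> SignalTrack:
    """Strict bedGraph: 4 columns, values >= 0, no overlapping segments."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed record") from None
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value")
            records.append((fields[0], start, end, value))
    try:
        return SignalTrack.from_records(records)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {name: uppercase sequence}; name is the first header token."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in genome:
            raise ParseError(f"{path}: duplicate header {name}")
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {name}")
        genome[name] = seq
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path: str | Path) -> list[PositionWeightMatrix]:
    """Parse MEME minimal format.

    Rows are renormalized when their sum is within 1e-3 of 1, else it is a
    format error; background frequencies default to uniform when the file has
    no background line.
    """
    background = np.full(4, 0.25)
    motifs: list[PositionWeightMatrix] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            tokens: list[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freq = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freq.get(b, 0.25) for b in _BASES])
            background = background / background.sum()
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= n:
                raise ParseError(f"{path}: motif {motif_id} has no matrix")
            header = lines[i]
            declared_w = None
            if "w=" in header:
                declared_w = int(header.split("w=")[1].split()[0])
            i += 1
            rows = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                parts = stripped.split()
                if len(parts) != 4:
                    raise ParseError(
                        f"{path}:{i + 1}: matrix row needs 4 columns"
                    )
                rows.append([float(x) for x in parts])
                i += 1
            probs = np.array(rows, dtype=float)
            if probs.size == 0:
                raise ParseError(f"{path}: motif {motif_id} has empty matrix")
            if declared_w is not None and probs.shape[0] != declared_w:
                raise ParseError(
                    f"{path}: motif {motif_id}: width {probs.shape[0]} "
                    f"does not match declared w={declared_w}"
                )
            sums = probs.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ParseError(
                    f"{path}: motif {motif_id}: row {bad} sums to {sums[bad]:.6f}"
                )
            probs = probs / sums[:, None]
            motifs.append(PositionWeightMatrix(motif_id, probs, background.copy()))
            continue
        i += 1
    return motifs


def write_meme_motifs(
    motifs: Sequence[PositionWeightMatrix], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                "A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg)
            )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_expression_tsv(
    path: str | Path, lineage_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    lineage_df = pd.read_csv(
        lineage_path, sep="\t", header=None, names=["sample", "lineage"],
        dtype=str,
    )
    lineage = dict(zip(lineage_df["sample"], lineage_df["lineage"]))
    return ExpressionMatrix(values, lineage)


def write_expression_tsv(
    expr: ExpressionMatrix, path: str | Path, lineage_path: str | Path
) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    with open(lineage_path, "w") as fh:
        for sample in expr.samples:
            fh.write(f"{sample}\t{expr.lineage[sample]}\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    genes = [
        GeneAnnotation(
            row.gene_id, row.symbol, row.chrom, row.strand, int(row.tss),
            bool(int(row.is_tf)),
        )
        for row in df.itertuples()
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate gene_id")
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\tstrand\ttss\tis_tf\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.strand}\t{g.tss}"
                f"\t{int(g.is_tf)}\n"
            )


def read_de_table(path: str | Path) -> DifferentialTable:
    return DifferentialTable(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))


def write_de_table(table: DifferentialTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a YAML key-value config; unknown keys and bad values are rejected
    with every offending key named."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
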