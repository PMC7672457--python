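"""End-to-end orchestration: SE call -> motif scan -> circuit -> occupancy ->
expression filters -> overlap statistics, with a reproducibility manifest.

Stage outputs are plain TSV/JSON so any stage can be rerun or inspected in
isolation; the manifest records the config snapshot, input/output checksums,
per-stage record counts and the seed, which fully determine a rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circuit import (
    build_edges,
    candidate_table,
    driver_constraint,
    enumerate_circuits,
    extend_regions,
)
from .core_io import (
    PipelineConfig,
    read_bed,
    read_bedgraph,
    read_de_table,
    read_expression_tsv,
    read_fasta,
    read_gene_table,
    read_meme_motifs,
)
from .expression import pearson_matrix, select_downregulated, specificity_topk
from .motifscan import spacing_stats
from .occupancy import (
    assign_occupancy,
    classify_elements,
    expression_by_class,
    occupancy_fractions,
    se_overlap_by_class,
    signal_profile,
)
from .overlap_stats import empirical_overlap_test, shared_fraction
from .superenhancer import (
    assign_to_genes,
    call_super_enhancers,
    rank_by_signal,
    se_assigned_tfs,
    stitch_peaks,
)

DRIVER_NAME = "EWS-FLI1"


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_full(
    input_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage on a bundle directory; returns the manifest dict."""
    cfg = config or PipelineConfig()
    cfg.validate()
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def require(name: str) -> Path:
        p = input_dir / name
        if not p.exists():
            raise FileNotFoundError(f"missing input file: {p}")
        return p

    # ---- load inputs ----
    inputs = {}
    for key in (
        "genome.fa", "genes.tsv", "h3k27ac_peaks.bed", "h3k4me1_peaks.bed",
        "h3k4me3_peaks.bed", "h3k27ac.bedgraph", "motifs.meme",
        "driver_peaks.bed", "expression.tsv", "lineages.tsv",
    ):
        inputs[key] = require(key)
    tf_peak_files = sorted(input_dir.glob("tf_peaks_*.bed"))
    de_files = sorted(input_dir.glob("de_*.tsv"))

    genome = read_fasta(inputs["genome.fa"])
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    genes = read_gene_table(inputs["genes.tsv"])
    k27_peaks = read_bed(inputs["h3k27ac_peaks.bed"])
    me1_peaks = read_bed(inputs["h3k4me1_peaks.bed"])
    me3_peaks = read_bed(inputs["h3k4me3_peaks.bed"])
    k27_track = read_bedgraph(inputs["h3k27ac.bedgraph"])
    motifs = {m.motif_id: m for m in read_meme_motifs(inputs["motifs.meme"])}
    driver_peaks = read_bed(inputs["driver_peaks.bed"])
    expr = read_expression_tsv(inputs["expression.tsv"], inputs["lineages.tsv"])
    counts["genes"] = len(genes)
    counts["h3k27ac_peaks"] = len(k27_peaks)

    # ---- stage: super-enhancer call ----
    try:
        tss_list = [(g.chrom, g.tss) for g in genes]
        regions = stitch_peaks(
            k27_peaks, cfg.se_stitch_bp, tss_list, cfg.tss_exclusion_bp
        )
        ranked = rank_by_signal(regions, k27_track)
        ses, cutoff = call_super_enhancers(ranked)
        ses = assign_to_genes(ses, genes, cfg.se_assign_window_bp)
        tf_set = se_assigned_tfs(ses, genes)
    except Exception as exc:  # noqa: BLE001
        raise StageError("se-call", exc) from exc
    counts["stitched_regions"] = len(ses)
    counts["super_enhancers"] = sum(se.is_super for se in ses)
    counts["se_assigned_tfs"] = len(tf_set)
    se_df = pd.DataFrame(
        {
            "chrom": [se.interval.chrom for se in ses],
            "start": [se.interval.start for se in ses],
            "end": [se.interval.end for se in ses],
            "rank": [se.rank for se in ses],
            "total_signal": [round(se.total_signal, 3) for se in ses],
            "is_super": [int(se.is_super) for se in ses],
            "assigned_genes": [",".join(se.assigned_genes) for se in ses],
        }
    ).sort_values("rank")
    se_df.to_csv(out_dir / "se_table.tsv", sep="\t", index=False)

    # ---- stage: circuit construction ----
    try:
        regions_by_tf = {}
        for tf in tf_set:
            ivs = [
                se.interval
                for se in ses
                if se.is_super and tf in se.assigned_genes
            ]
            regions_by_tf[tf] = extend_regions(
                ivs, cfg.se_extension_bp, chrom_lengths
            )
        graph = build_edges(
            tf_set, motifs, regions_by_tf, genome,
            pvalue_threshold=cfg.fimo_pvalue,
        )
        graph.driver_ok = {
            tf
            for tf in tf_set
            if driver_constraint(
                regions_by_tf[tf], genome, driver_peaks,
                ggaa_min_units=cfg.ggaa_min_units,
            )
        }
        circuits = enumerate_circuits(graph)
        cand = candidate_table(circuits, graph, min_size=2)
    except Exception as exc:  # noqa: BLE001
        raise StageError("build", exc) from exc
    counts["edges"] = len(graph.edges)
    counts["circuits"] = len(circuits)
    edges_df = pd.DataFrame(
        sorted(
            (a, b, len(h)) for (a, b), h in graph.edges.items()
        ),
        columns=["source", "target", "n_hits"],
    )
    edges_df.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "rank": range(1, len(circuits) + 1),
            "size": [c.size for c in circuits],
            "total_evidence": [c.total_evidence for c in circuits],
            "members": [",".join(sorted(c.members)) for c in circuits],
        }
    ).to_csv(out_dir / "circuits.tsv", sep="\t", index=False)
    cand.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)

    top_members = sorted(circuits[0].members) if circuits else []

    # motif spacing within the top circuit's regions (distinct motifs only)
    spacing = None
    if len(top_members) >= 2:
        cluster_hits = [
            h
            for (a, b), hits in graph.edges.items()
            if a in top_members and b in top_members
            for h in hits
        ]
        # per-region nearest-neighbor gaps
        if cluster_hits:
            spacing = spacing_stats(cluster_hits)
    counts["top_circuit_size"] = len(top_members)

    # ---- stage: occupancy ----
    try:
        factor_peaks = {DRIVER_NAME: driver_peaks}
        for f in tf_peak_files:
            factor_peaks[f.stem.replace("tf_peaks_", "")] = read_bed(f)
        elements, dropped = classify_elements(
            k27_peaks, me3_peaks, me1_peaks, genes, cfg.promoter_window_bp
        )
        elements = assign_occupancy(elements, factor_peaks)
        factors = list(factor_peaks)
        summary = occupancy_fractions(elements, factors)
        groups: dict[str, list] = {}
        card_names = {0: "unbound", 1: "solo", 2: "dual", 3: "trio", 4: "quad"}
        for el in elements:
            k = sum(el.occupancy)
            groups.setdefault(card_names.get(k, f"{k}-fold"), []).append(el)
        profiles = signal_profile(
            groups, k27_track, cfg.profile_halfwidth_bp, cfg.profile_bins
        )
        se_overlap = se_overlap_by_class(groups, ses)
        promoter_groups = {
            label: [e for e in els if e.element_class == "promoter"]
            for label, els in groups.items()
        }
        promoter_groups = {k: v for k, v in promoter_groups.items() if v}
        pairs = (
            [("trio", "solo")]
            if "trio" in promoter_groups and "solo" in promoter_groups
            else []
        )
        _, quartiles, exp_pvals = expression_by_class(
            promoter_groups, expr, test_pairs=pairs
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("occupancy", exc) from exc
    counts["elements"] = len(elements)
    counts["elements_dropped"] = dropped
    el_df = pd.DataFrame(
        {
            "chrom": [e.interval.chrom for e in elements],
            "start": [e.interval.start for e in elements],
            "end": [e.interval.end for e in elements],
            "class": [e.element_class for e in elements],
            "gene": [e.assigned_gene for e in elements],
            "pattern": [
                "+".join(f for f, b in zip(factors, e.occupancy) if b) or "none"
                for e in elements
            ],
        }
    )
    el_df.to_csv(out_dir / "elements.tsv", sep="\t", index=False)
    prof_df = pd.DataFrame(
        {k: np.round(v, 4) for k, v in sorted(profiles.items())}
    )
    prof_df.to_csv(out_dir / "profiles.tsv", sep="\t", index=False)

    # ---- stage: expression filters ----
    try:
        target_lineage = expr.lineage[expr.samples[0]]
        spec_rows = []
        for tf in tf_set:
            if tf in expr.values.index:
                r = specificity_topk(expr, tf, target_lineage, cfg.specificity_topk)
                spec_rows.append(
                    {"tf": tf, "target_rank": r.target_rank,
                     "passes": int(r.passes)}
                )
        corr = None
        lin_samples = expr.samples_of(target_lineage)
        corr_members = [t for t in top_members if t in expr.values.index]
        if len(corr_members) >= 2 and len(lin_samples) >= 3:
            corr = pearson_matrix(expr, corr_members, lin_samples)
    except Exception as exc:  # noqa: BLE001
        raise StageError("expr-filter", exc) from exc
    pd.DataFrame(spec_rows).to_csv(
        out_dir / "specificity.tsv", sep="\t", index=False
    )
    if corr is not None:
        corr.round(4).to_csv(out_dir / "correlation.tsv", sep="\t")

    # ---- stage: overlap statistics ----
    overlap_report: dict = {}
    try:
        de_sets = []
        for f in de_files:
            table = read_de_table(f)
            label = f.stem.replace("de_", "")
            de_sets.append(
                select_downregulated(
                    table, cfg.de_padj, cfg.de_abs_lfc, label=label
                )
            )
        if len(de_sets) >= 2:
            from .expression import GeneSet

            universe = GeneSet(
                "expressed",
                frozenset(
                    expr.values.index[expr.values.mean(axis=1) > cfg.tpm_min]
                ),
            )
            result = empirical_overlap_test(
                de_sets, universe, n_perm=cfg.n_perm, seed=cfg.seed
            )
            shared = shared_fraction(de_sets)
            overlap_report = {
                "observed_intersection": result.observed_intersection,
                "n_perm": result.n_perm,
                "pvalue": result.pvalue,
                "shared_fraction": {k: round(v, 4) for k, v in shared.items()},
                "set_sizes": {s.label: len(s) for s in de_sets},
                "universe_size": len(universe.genes),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError("overlap", exc) from exc
    counts["de_tables"] = len(de_files)

    # ---- manifest ----
    report = {
        "super_enhancer_cutoff": round(cutoff, 3),
        "top_circuit": top_members,
        "bound_percent": {
            cls: summary.per_class[cls]["bound_percent"]
            for cls in summary.per_class
        },
        "se_overlap_by_group": {k: round(v, 4) for k, v in sorted(se_overlap.items())},
        "expression_quartiles": {
            k: [round(float(x), 4) for x in v] for k, v in sorted(quartiles.items())
        },
        "expression_test_pvalues": {
            f"{a}_vs_{b}": (None if np.isnan(p) else round(p, 6))
            for (a, b), p in exp_pvals.items()
        },
        "motif_spacing_bp": (
            {"mean": round(spacing[0], 2), "min": spacing[1], "max": spacing[2]}
            if spacing
            else None
        ),
        "occupancy": summary.per_class,
        "overlap": overlap_report,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    output_files = sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {name: _sha256(path) for name, path in sorted(inputs.items())},
        "counts": counts,
        "outputs": {name: _sha256(out_dir / name) for name in output_files},
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return manifest
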