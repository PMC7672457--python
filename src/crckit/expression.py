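"""Expression-based candidate filters and DE gene-set construction.

Lineage specificity follows the CCLE-style "top k among all cell types"
filter: per-lineage mean TPM is ranked and a candidate passes when its
target lineage ranks within the top k. Ties take the worst (largest) rank
shared by all tied lineages, which is the conservative reading. Pairwise
Pearson correlation across a sample subset captures the co-expression
expected of co-regulated circuit members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DifferentialTable, ExpressionMatrix


@dataclass(frozen=True)
class SpecificityResult:
    gene_id: str
    lineage_means: dict[str, float]
    target_rank: int
    passes: bool


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def specificity_topk(
    expr: ExpressionMatrix,
    gene: str,
    target_lineage: str,
    k: int,
    per_sample: bool = False,
) -> SpecificityResult:
    """Rank lineages by mean TPM of ``gene`` (descending); worst-tie rule.

    ``per_sample`` ranks individual samples instead of lineage means (the
    alternative reading of a cell-line panel ranking).
    """
    if gene not in expr.values.index:
        raise KeyError(f"unknown gene: {gene}")
    if target_lineage not in expr.lineages:
        raise KeyError(f"unknown lineage: {target_lineage}")
    row = expr.values.loc[gene]
    if per_sample:
        means = {s: float(row[s]) for s in expr.samples}
        target_value = max(
            float(row[s]) for s in expr.samples_of(target_lineage)
        )
        values = np.array(list(means.values()))
        rank = int((values > target_value).sum() + (values == target_value).sum())
        lineage_means = {
            lin: float(np.mean([row[s] for s in expr.samples_of(lin)]))
            for lin in expr.lineages
        }
        return SpecificityResult(gene, lineage_means, rank, rank <= k)
    lineage_means = {
        lin: float(np.mean([row[s] for s in expr.samples_of(lin)]))
        for lin in expr.lineages
    }
    target_value = lineage_means[target_lineage]
    values = np.array(list(lineage_means.values()))
    # all tied lineages share the worst rank
    rank = int((values > target_value).sum() + (values == target_value).sum())
    return SpecificityResult(gene, lineage_means, rank, rank <= k)


def pearson_matrix(
    expr: ExpressionMatrix,
    genes: list[str],
    sample_subset: list[str],
) -> pd.DataFrame:
    """Pairwise Pearson r over ``sample_subset``; zero-variance genes get
    missing (NaN) correlations, diagonal 1 where defined."""
    if len(sample_subset) < 3:
        raise ValueError("pearson_matrix requires >= 3 samples")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"unknown genes: {missing}")
    data = expr.values.loc[genes, sample_subset].to_numpy(dtype=float)
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.asarray(corr, dtype=float)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    return pd.DataFrame(corr, index=genes, columns=genes)


def select_downregulated(
    de: DifferentialTable,
    padj_max: float = 0.05,
    lfc_cut: float = 0.5,
    mode: str = "standard",
    strict_lfc: float = 1.0,
    expr: ExpressionMatrix | None = None,
    tpm_min: float = 0.5,
    label: str = "down",
) -> GeneSet:
    """Downregulated gene set at the published thresholds.

    standard: padj < padj_max and log2fc < -lfc_cut (the negative side of
    the absolute fold-change rule). strict: padj < padj_max and
    log2fc < -strict_lfc, with the universe restricted to genes whose mean
    TPM exceeds ``tpm_min`` when an expression matrix is supplied.
    """
    if mode not in {"standard", "strict"}:
        raise ValueError("mode must be standard or strict")
    df = de.frame
    cut = lfc_cut if mode == "standard" else strict_lfc
    mask = (df["padj"] < padj_max) & (df["log2fc"] < -cut)
    genes = set(df.loc[mask, "gene_id"])
    if mode == "strict" and expr is not None:
        expressed = set(
            expr.values.index[expr.values.mean(axis=1) > tpm_min]
        )
        genes &= expressed
    return GeneSet(label, frozenset(genes))


def knockdown_effect_heatmap(
    de_tables: dict[str, DifferentialTable],
    genes: list[str],
    padj_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x perturbations log2 fold-change matrix plus significance flags.

    A gene missing from a table yields a missing cell (NaN / False) with a
    warning.
    """
    import warnings

    lfc = pd.DataFrame(index=genes, columns=list(de_tables), dtype=float)
    sig = pd.DataFrame(False, index=genes, columns=list(de_tables))
    for pert, table in de_tables.items():
        frame = table.frame.set_index("gene_id")
        for gene in genes:
            if gene not in frame.index:
                warnings.warn(f"{gene} missing from {pert} table")
                continue
            lfc.loc[gene, pert] = float(frame.loc[gene, "log2fc"])
            sig.loc[gene, pert] = bool(frame.loc[gene, "padj"] < padj_max)
    return lfc, sig
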