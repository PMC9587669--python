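"""Derivation of the conserved SE-associated gene signatures.

cSE: genes called SE-associated in at least ``min_lines`` tumor cell lines.
oSE: intersection of cSE with the tissue-derived SE gene list (tSE).
vSE: oSE members that are subtype-specifically upregulated (vs normal
cerebellum in >= 1 dataset at log2FC > 0.6, or vs the other subtypes in
>= 3 datasets at log2FC > 0.2, both at FDR < 0.05) AND tumor-dependent
(CERES gene effect < -0.1 in >= 2 cell lines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DependencyMatrix, GeneSignature

logger = logging.getLogger("secircuit")

#: contrast labels understood by :func:`filter_vse`
NC_CONTRAST = "vs_nc"
SUBTYPE_CONTRAST = "vs_subtypes"


@dataclass(frozen=True)
class VSECriteria:
    """Thresholds for the vital-SE (vSE) filter.

    Inequalities are strict, exactly as printed in the originating criteria:
    log2FC > the cut and FDR < fdr_max for expression; CERES < ceres_max for
    dependency. The CERES cutoff of -0.1 (rather than the conventional -0.5)
    keeps moderately-depleting lineage oncogenes such as CRX and NRL.
    """

    nc_log2fc_min: float = 0.6
    nc_min_datasets: int = 1
    subtype_log2fc_min: float = 0.2
    subtype_min_datasets: int = 3
    fdr_max: float = 0.05
    ceres_max: float = -0.1
    ceres_min_lines: int = 2

    def __post_init__(self) -> None:
        for v in (self.nc_log2fc_min, self.subtype_log2fc_min,
                  self.fdr_max, self.ceres_max):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")
        if self.nc_min_datasets < 1 or self.subtype_min_datasets < 1:
            raise ValueError("min_datasets must be >= 1")
        if self.ceres_min_lines < 1:
            raise ValueError("ceres_min_lines must be >= 1")


def recurrent_signature(
    per_line_gene_sets: dict[str, set[str]],
    min_lines: int = 3,
    name: str = "cSE",
) -> GeneSignature:
    """Genes present in at least ``min_lines`` of the per-line gene sets."""
    if min_lines < 1:
        raise ValueError("min_lines must be >= 1")
    if min_lines > len(per_line_gene_sets):
        raise ValueError(
            f"min_lines={min_lines} exceeds the {len(per_line_gene_sets)} input sets"
        )
    counts: dict[str, int] = {}
    for genes in per_line_gene_sets.values():
        for g in genes:
            g = str(g).upper()
            counts[g] = counts.get(g, 0) + 1
    genes = frozenset(g for g, c in counts.items() if c >= min_lines)
    return GeneSignature(
        name=name,
        genes=genes,
        provenance=(
            f"recurrent in >= {min_lines} of {len(per_line_gene_sets)} lines "
            f"({', '.join(sorted(per_line_gene_sets))})"
        ),
    )


def intersect_signatures(a: GeneSignature, b: GeneSignature, name: str) -> GeneSignature:
    return a.intersect(b, name=name)


def filter_vse(
    ose: GeneSignature,
    de_results: dict[str, tuple[str, pd.DataFrame]],
    dependency: DependencyMatrix,
    criteria: VSECriteria = VSECriteria(),
    cell_line_whitelist: list[str] | None = None,
    name: str = "vSE",
) -> tuple[GeneSignature, pd.DataFrame]:
    """Apply the expression + dependency filter that defines the vSE set.

    ``de_results`` maps dataset name to (contrast_type, DE table) where
    contrast_type is ``"vs_nc"`` or ``"vs_subtypes"`` and the table is
    indexed by gene symbol with ``log2fc`` and ``fdr`` columns. A gene
    missing from a dataset simply does not count toward that dataset; a gene
    missing from the dependency matrix counts zero dependent lines.

    Returns the vSE signature and a per-gene evidence table (one row per oSE
    gene) recording every per-dataset pass/fail, the dependent-line count,
    and the overall verdict.
    """
    dep_vals = dependency.values
    if cell_line_whitelist is not None:
        missing = set(cell_line_whitelist) - set(dep_vals.columns)
        if missing:
            raise ValueError(f"whitelisted cell lines absent from matrix: {sorted(missing)}")
        dep_vals = dep_vals[list(cell_line_whitelist)]

    for ds, (contrast, _tbl) in de_results.items():
        if contrast not in {NC_CONTRAST, SUBTYPE_CONTRAST}:
            raise ValueError(
                f"dataset {ds!r}: contrast must be {NC_CONTRAST!r} or {SUBTYPE_CONTRAST!r}"
            )

    rows = []
    passing = set()
    for gene in sorted(ose.genes):
        row: dict[str, object] = {"gene": gene}
        nc_hits = 0
        sub_hits = 0
        for ds, (contrast, tbl) in de_results.items():
            cut = (criteria.nc_log2fc_min if contrast == NC_CONTRAST
                   else criteria.subtype_log2fc_min)
            ok = False
            if gene in tbl.index:
                rec = tbl.loc[gene]
                ok = bool(rec["log2fc"] > cut and rec["fdr"] < criteria.fdr_max)
            row[f"pass_{ds}"] = ok
            if ok:
                if contrast == NC_CONTRAST:
                    nc_hits += 1
                else:
                    sub_hits += 1
        if gene in dep_vals.index:
            dep_lines = int((dep_vals.loc[gene] < criteria.ceres_max).sum())
        else:
            logger.info("filter_vse: %s absent from dependency matrix", gene)
            dep_lines = 0
        expr_ok = (nc_hits >= criteria.nc_min_datasets
                   or sub_hits >= criteria.subtype_min_datasets)
        dep_ok = dep_lines >= criteria.ceres_min_lines
        row.update(
            nc_datasets_passing=nc_hits,
            subtype_datasets_passing=sub_hits,
            dependent_lines=dep_lines,
            expression_pass=expr_ok,
            dependency_pass=dep_ok,
            vse=expr_ok and dep_ok,
        )
        rows.append(row)
        if expr_ok and dep_ok:
            passing.add(gene)

    evidence = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    signature = GeneSignature(
        name=name,
        genes=frozenset(passing),
        provenance=(
            f"oSE filtered by expression (log2FC>{criteria.nc_log2fc_min} vs NC in "
            f">={criteria.nc_min_datasets} ds OR log2FC>{criteria.subtype_log2fc_min} "
            f"vs subtypes in >={criteria.subtype_min_datasets} ds, FDR<{criteria.fdr_max}) "
            f"AND CERES<{criteria.ceres_max} in >={criteria.ceres_min_lines} lines"
        ),
    )
    return signature, evidence


def threshold_intersect_de(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    direction: str,
    log2fc_cut: float,
    fdr_cut: float = 0.05,
    min_mean_expr: float | None = None,
    mean_expr_column: str = "mean_expr",
) -> set[str]:
    """Genes passing directional DE thresholds in both tables.

    direction 'up' keeps log2fc > log2fc_cut, 'down' keeps log2fc <
    log2fc_cut, each with fdr < fdr_cut; ``min_mean_expr`` optionally
    applies an active-expression floor (>= on ``mean_expr_column``).
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")

    def passing(tbl: pd.DataFrame) -> set[str]:
        lfc = tbl["log2fc"]
        mask = (lfc > log2fc_cut) if direction == "up" else (lfc < log2fc_cut)
        mask &= tbl["fdr"] < fdr_cut
        if min_mean_expr is not None:
            mask &= tbl[mean_expr_column] >= min_mean_expr
        return {str(g).upper() for g in tbl.index[mask]}

    return passing(de_a) & passing(de_b)
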