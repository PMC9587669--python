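"""Core domain types shared across the pipeline.

Coordinates are 0-based, half-open throughout (BED convention). A TSS is a
single base position; for minus-strand genes it is the annotated transcript
end, so promoter flanks always centre on the true start of transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("secircuit")

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """An H3K27Ac enrichment region with normalized signal densities.

    Densities are in reads per million per base pair (rpm/bp); the input
    density comes from the matched whole-cell-extract control and is 0 when
    no control was provided.
    """

    interval: GenomicInterval
    sample_density: float = 0.0
    input_density: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name, v in (("sample_density", self.sample_density),
                        ("input_density", self.input_density)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def signal(self) -> float:
        """Background-subtracted signal (rpm), clamped at zero."""
        return max(0.0, self.sample_density - self.input_density) * self.interval.length

    def sort_key(self):
        return (self.interval.chrom, self.interval.start, self.interval.end)


def sort_peaks(peaks: list[Peak]) -> list[Peak]:
    return sorted(peaks, key=Peak.sort_key)


@dataclass
class TSSTable:
    """One transcription start site per gene symbol.

    Backed by a DataFrame indexed by (uppercase) gene symbol with columns
    ``chrom``, ``tss`` (0-based bp) and ``strand``. Duplicate symbols keep
    the first entry; the rest are logged and dropped.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "tss", "strand"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"TSSTable requires columns {required}")
        idx = self.table.index.astype(str).str.upper()
        tbl = self.table.copy()
        tbl.index = idx
        dup = tbl.index.duplicated(keep="first")
        if dup.any():
            logger.warning(
                "TSSTable: dropping %d duplicate gene symbols (%s ...)",
                dup.sum(), ", ".join(tbl.index[dup][:5]),
            )
            tbl = tbl[~dup]
        tbl["tss"] = tbl["tss"].astype(np.int64)
        if (tbl["tss"] < 0).any():
            raise ValueError("TSS positions must be >= 0")
        self.table = tbl

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.table.index

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def position(self, gene: str) -> tuple[str, int, str]:
        row = self.table.loc[gene.upper()]
        return str(row["chrom"]), int(row["tss"]), str(row["strand"])

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.table.groupby("chrom", sort=True)}


@dataclass(frozen=True)
class GeneSignature:
    """A named gene-symbol set with free-text provenance.

    Symbols are uppercase-normalized so that set algebra across datasets with
    mixed-case symbols behaves predictably.
    """

    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        object.__setattr__(
            self, "genes", frozenset(str(g).upper() for g in self.genes)
        )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in self.genes

    def intersect(self, other: "GeneSignature", name: str | None = None) -> "GeneSignature":
        return GeneSignature(
            name=name or f"{self.name}&{other.name}",
            genes=self.genes & other.genes,
            provenance=f"intersection of [{self.provenance}] and [{other.provenance}]",
        )

    def rename(self, name: str) -> "GeneSignature":
        return replace(self, name=name)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with per-sample group labels.

    ``values`` is genes x samples; ``scale`` declares whether values are
    already log2 or linear FPKM. Duplicate gene symbols are collapsed to the
    row with the highest mean expression (probe-collapse convention).
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = "log2"  # "log2" or "fpkm"

    def __post_init__(self) -> None:
        if self.scale not in {"log2", "fpkm"}:
            raise ValueError("scale must be 'log2' or 'fpkm'")
        vals = self.values.copy()
        vals.index = vals.index.astype(str).str.upper()
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if vals.index.duplicated().any():
            means = vals.mean(axis=1)
            order = np.argsort(-means.to_numpy(), kind="stable")
            vals = vals.iloc[order]
            dup = vals.index.duplicated(keep="first")
            logger.warning(
                "ExpressionMatrix: collapsed %d duplicate symbols by highest mean",
                dup.sum(),
            )
            vals = vals[~dup].sort_index()
        self.values = vals
        groups = self.groups.reindex(vals.columns)
        if groups.isna().any():
            missing = list(groups.index[groups.isna()])
            raise ValueError(f"samples without group label: {missing[:5]}")
        self.groups = groups.astype(str)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def log2(self) -> "ExpressionMatrix":
        """Return a log2-scale view (log2(x+1) if currently FPKM)."""
        if self.scale == "log2":
            return self
        return ExpressionMatrix(
            values=np.log2(self.values + 1.0), groups=self.groups, scale="log2"
        )


@dataclass
class DependencyMatrix:
    """Gene x cell-line CERES gene-effect scores (negative = dependent)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.copy()
        vals.index = vals.index.astype(str).str.upper()
        if vals.columns.duplicated().any():
            raise ValueError("cell-line ids must be unique")
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise ValueError("CERES scores must be finite")
        if vals.index.duplicated().any():
            vals = vals[~vals.index.duplicated(keep="first")]
        self.values = vals

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SurvivalTable:
    """Per-patient follow-up time (months), event indicator and score."""

    table: pd.DataFrame  # columns: time, event, plus any score columns

    def __post_init__(self) -> None:
        if not {"time", "event"}.issubset(self.table.columns):
            raise ValueError("SurvivalTable requires 'time' and 'event' columns")
        t = self.table["time"].to_numpy(dtype=float)
        e = self.table["event"].to_numpy()
        if (t <= 0).any() or not np.isfinite(t).all():
            raise ValueError("times must be finite and > 0")
        if not set(np.unique(e)).issubset({0, 1}):
            raise ValueError("event must be binary 0/1")

    @property
    def time(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)


@dataclass
class StitchedEnhancer:
    """Constituent peaks merged within the stitching distance.

    ``signal`` is the sum over constituents of background-subtracted density
    times constituent length (rpm); gaps contribute nothing. ``rank`` is
    ascending in signal (1 = lowest) as conventionally plotted.
    """

    interval: GenomicInterval
    constituents: list[Peak] = field(default_factory=list)
    signal: float = 0.0
    rank: int = 0
    is_super: bool = False

    @property
    def num_constituents(self) -> int:
        return len(self.constituents)

    @property
    def input_signal(self) -> float:
        return float(
            sum(p.input_density * p.interval.length for p in self.constituents)
        )
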