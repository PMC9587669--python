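"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) both in
memory and on disk; GTF input (1-based, closed) is converted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DependencyMatrix,
    ExpressionMatrix,
    GenomicInterval,
    Peak,
    StitchedEnhancer,
    SurvivalTable,
    TSSTable,
    sort_peaks,
)

logger = logging.getLogger("secircuit")

ENHANCER_TABLE_COLUMNS = [
    "region_id", "chrom", "start", "end", "num_constituents",
    "signal", "input_signal", "rank", "is_super",
]


class RecordError(ValueError):
    """A malformed record, carrying the 1-based line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# bedGraph signal

class BedGraphSignal:
    """Base-resolution signal held as per-chromosome interval arrays.

    Used to average a density track over arbitrary peaks; bases not covered
    by any bedGraph interval contribute zero to the average.
    """

    def __init__(self, frame: pd.DataFrame):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in frame.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            if (ends <= starts).any():
                raise ValueError(f"bedGraph: end <= start on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"bedGraph: overlapping intervals on {chrom}")
            self._chroms[str(chrom)] = (
                starts, ends, grp["value"].to_numpy(float)
            )

    @classmethod
    def read(cls, path) -> "BedGraphSignal":
        frame = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        return cls(frame)

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean signal over [start, end)."""
        if chrom not in self._chroms:
            logger.warning("bedGraph: chrom %s not in signal track; density 0", chrom)
            return 0.0
        starts, ends, values = self._chroms[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        ov = (np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start))
        ov = np.clip(ov, 0, None)
        return float((ov * values[lo:hi]).sum() / (end - start))


# ---------------------------------------------------------------------------
# peaks

def _read_bed3(path) -> list[tuple[str, int, int, int]]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise RecordError(path, line_no, f"expected >= 3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RecordError(path, line_no, f"non-integer coordinates: {exc}") from None
            if end <= start or start < 0:
                raise RecordError(path, line_no, f"invalid interval [{start}, {end})")
            out.append((chrom, start, end, line_no))
    return out


def _density_lookup(path) -> dict[tuple[str, int, int], float]:
    """Per-peak density TSV: chrom, start, end, density (rpm/bp)."""
    frame = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "density"], dtype={"chrom": str},
    )
    if frame["density"].dtype == object:  # header row present
        frame = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
        frame.columns = ["chrom", "start", "end", "density"]
    return {
        (str(r.chrom), int(r.start), int(r.end)): float(r.density)
        for r in frame.itertuples()
    }


def _is_bedgraph(path) -> bool:
    return str(path).endswith((".bdg", ".bedgraph", ".bedGraph"))


def read_peaks(path, signal_path=None, input_path=None, sample_id: str = "") -> list[Peak]:
    """Read a BED3 peak file and attach sample/input signal densities.

    ``signal_path``/``input_path`` are either base-resolution bedGraph tracks
    (averaged length-weighted over each peak) or per-peak density TSVs
    (chrom, start, end, density). Missing control means input density 0.
    """
    records = _read_bed3(path)
    peaks: list[Peak] = []

    def density_fn(sig_path):
        if sig_path is None:
            return lambda c, s, e: 0.0
        if _is_bedgraph(sig_path):
            track = BedGraphSignal.read(sig_path)
            return track.mean_over
        lookup = _density_lookup(sig_path)

        def per_peak(c, s, e):
            key = (c, s, e)
            if key not in lookup:
                logger.warning("no density for peak %s:%d-%d; using 0", c, s, e)
                return 0.0
            return lookup[key]

        return per_peak

    sample_fn = density_fn(signal_path)
    input_fn = density_fn(input_path)
    for chrom, start, end, _line in records:
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                sample_density=sample_fn(chrom, start, end),
                input_density=input_fn(chrom, start, end),
                sample_id=sample_id,
            )
        )
    return sort_peaks(peaks)


def write_peaks(peaks: list[Peak], bed_path, density_path=None) -> None:
    with open(bed_path, "w") as fh:
        fh.write("# BED3, 0-based half-open\n")
        for p in peaks:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\n")
    if density_path is not None:
        with open(density_path, "w") as fh:
            for p in peaks:
                fh.write(
                    f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                    f"\t{p.sample_density:.6g}\n"
                )


# ---------------------------------------------------------------------------
# TSS annotation

def read_tss_table(path) -> TSSTable:
    """Read TSSs from a TSV (gene, chrom, tss, strand) or a GTF.

    GTF gene records are converted to 0-based TSS: start−1 on the plus
    strand, end−1 on the minus strand (the true start of transcription).
    """
    if str(path).endswith((".gtf", ".gtf.gz")):
        return _read_tss_gtf(path)
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    required = {"gene", "chrom", "tss", "strand"}
    if not required.issubset(frame.columns):
        raise ValueError(f"TSS TSV requires columns {required}")
    return TSSTable(frame.set_index("gene")[["chrom", "tss", "strand"]])


def _read_tss_gtf(path) -> TSSTable:
    import pyranges as pr

    df = pr.read_gtf(path).df  # already 0-based half-open
    df = df[df["Feature"] == "gene"]
    name_col = "gene_name" if "gene_name" in df.columns else "gene_id"
    names = df[name_col]
    if name_col != "gene_id" and "gene_id" in df.columns:
        names = names.fillna(df["gene_id"])
    tss = np.where(df["Strand"] == "-", df["End"] - 1, df["Start"])
    frame = pd.DataFrame({
        "gene": names.to_numpy(),
        "chrom": df["Chromosome"].astype(str).to_numpy(),
        "tss": tss,
        "strand": df["Strand"].astype(str).to_numpy(),
    })
    return TSSTable(frame.set_index("gene"))


def write_tss_table(tss: TSSTable, path) -> None:
    out = tss.table.reset_index(names="gene")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a GMT file (name, description, tab-separated symbols)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise RecordError(path, line_no, "GMT needs >= 2 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise RecordError(path, line_no, f"duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gene_sets(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# enhancer tables

def write_enhancer_table(enhancers: list[StitchedEnhancer], path, bed_path=None) -> None:
    """Write a ROSE-style ranked enhancer TSV (plus optional SE BED6)."""
    rows = []
    for e in enhancers:
        rows.append({
            "region_id": f"{e.interval.chrom}:{e.interval.start}-{e.interval.end}",
            "chrom": e.interval.chrom,
            "start": e.interval.start,
            "end": e.interval.end,
            "num_constituents": e.num_constituents,
            "signal": e.signal,
            "input_signal": e.input_signal,
            "rank": e.rank,
            "is_super": int(e.is_super),
        })
    frame = pd.DataFrame(rows, columns=ENHANCER_TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# ROSE-style stitched enhancer table; coordinates 0-based half-open\n")
        frame.to_csv(fh, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            fh.write("# BED6 of super-enhancer regions, 0-based half-open\n")
            for e in enhancers:
                if e.is_super:
                    fh.write(
                        f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}"
                        f"\tSE_rank_{e.rank}\t{e.signal:.4f}\t.\n"
                    )


def read_enhancer_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# matrices and tables

def read_expression_matrix(path, groups_path=None, scale: str = "log2") -> ExpressionMatrix:
    """Read a gene x sample TSV (first column = symbol, header = sample ids).

    ``groups_path`` is a two-column TSV (sample, group); without it every
    sample is labelled 'NA' which most downstream operations will reject.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if groups_path is not None:
        grp = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        grp = pd.Series("NA", index=values.columns)
    return ExpressionMatrix(values=values, groups=grp, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path, groups_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    if groups_path is not None:
        matrix.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def read_dependency_matrix(path) -> DependencyMatrix:
    sep = "," if str(path).endswith(".csv") else "\t"
    return DependencyMatrix(pd.read_csv(path, sep=sep, index_col=0))


def read_survival_table(path) -> SurvivalTable:
    return SurvivalTable(pd.read_csv(path, sep="\t"))


def write_survival_table(table: SurvivalTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def read_dose_response(path) -> pd.DataFrame:
    """Dose-response TSV: drug, dose (or dose_1/dose_2 + drug_1/drug_2), viability."""
    frame = pd.read_csv(path, sep="\t")
    via_cols = [c for c in frame.columns if c.startswith("viability")]
    if not via_cols:
        raise ValueError("dose-response table requires a 'viability' column")
    v = frame[via_cols[0]].to_numpy(float)
    if ((v < -0.05) | (v > 1.05)).any():
        raise ValueError("viability must lie in [0, 1] (small overshoot tolerated)")
    frame[via_cols[0]] = np.clip(v, 0.0, 1.0)
    return frame
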