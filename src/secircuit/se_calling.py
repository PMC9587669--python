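"""Rank ordering of super-enhancers (ROSE-style).

The pipeline is: drop constituent peaks whose midpoint falls in a promoter
window (TSS +/- flank), stitch remaining peaks whose edge-to-edge gap is
within the stitching distance, quantify each stitched region as the sum of
background-subtracted constituent signal, rank regions by ascending signal,
and split super from typical enhancers at the tangent point of the ranked
curve ("hockey stick"): the rank where a line of slope (max-min)/N touches
the curve from below. Genes are assigned to enhancers by TSS proximity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import GeneSignature, GenomicInterval, Peak, StitchedEnhancer, TSSTable, sort_peaks

logger = logging.getLogger("secircuit")

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_PROMOTER_FLANK = 2_500
DEFAULT_GENE_WINDOW = 50_000


def exclude_promoter_peaks(
    peaks: list[Peak], tss_table: TSSTable, flank: int = DEFAULT_PROMOTER_FLANK
) -> list[Peak]:
    """Drop peaks whose midpoint lies within [tss - flank, tss + flank].

    The window is closed on both sides; order of surviving peaks is kept.
    """
    if len(tss_table) == 0:
        raise ValueError("tss_table must be non-empty")
    by_chrom = {
        chrom: np.sort(grp["tss"].to_numpy(np.int64))
        for chrom, grp in tss_table.by_chrom().items()
    }
    kept = []
    for p in peaks:
        tss = by_chrom.get(p.interval.chrom)
        if tss is None:
            kept.append(p)
            continue
        mid = p.interval.midpoint
        i = np.searchsorted(tss, mid)
        near = min(
            (abs(mid - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss)),
            default=np.inf,
        )
        if near > flank:
            kept.append(p)
    return kept


def stitch_peaks(
    peaks: list[Peak], stitch_distance: int = DEFAULT_STITCH_DISTANCE
) -> list[StitchedEnhancer]:
    """Merge same-chromosome peaks with edge-to-edge gap <= stitch_distance.

    Merging is transitive and inclusive of the exact stitch distance;
    the operation is idempotent and independent of input order.
    """
    if not peaks:
        return []
    peaks = sort_peaks(peaks)
    enhancers: list[StitchedEnhancer] = []
    group: list[Peak] = [peaks[0]]
    cur_end = peaks[0].interval.end

    def flush(members: list[Peak]) -> None:
        interval = GenomicInterval(
            members[0].interval.chrom,
            members[0].interval.start,
            max(m.interval.end for m in members),
        )
        enh = StitchedEnhancer(interval=interval, constituents=list(members))
        enh.signal = quantify_signal(enh)
        enhancers.append(enh)

    for p in peaks[1:]:
        same = p.interval.chrom == group[0].interval.chrom
        if same and p.interval.start - cur_end <= stitch_distance:
            group.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            flush(group)
            group = [p]
            cur_end = p.interval.end
    flush(group)
    return enhancers


def quantify_signal(enhancer: StitchedEnhancer) -> float:
    """Sum of max(0, sample - input) density x length over constituents (rpm)."""
    return float(sum(p.signal for p in enhancer.constituents))


def hockey_stick_cutoff(signals) -> tuple[float, int]:
    """Locate the super-enhancer cutoff on the ranked signal curve.

    Signals are sorted ascending (negatives clamped to 0) and a line of
    slope (max - min) / N is slid along the curve; the cutoff rank is where
    the line is tangent from below — equivalently the rank minimizing the
    number of points on or below the line, i.e. the argmin of the residual
    signal_i - slope * i. Ties resolve to the largest rank (fewest SEs).
    Returns (cutoff_signal, cutoff_rank) with rank 1-based ascending;
    enhancers with signal strictly above cutoff_signal are super. A flat
    curve (max == min) yields (max, N): zero super-enhancers.
    """
    y = np.sort(np.clip(np.asarray(signals, dtype=float), 0.0, None))
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 signals")
    if y[-1] == y[0]:
        return float(y[-1]), n
    slope = (y[-1] - y[0]) / n
    residual = y - slope * np.arange(n)
    best = int(np.flatnonzero(residual == residual.min())[-1])
    return float(y[best]), best + 1


def rank_and_classify(enhancers: list[StitchedEnhancer]) -> tuple[float, int]:
    """Assign ascending ranks in place and flag super-enhancers.

    Position ties are broken by genomic coordinate so ranking is a
    deterministic permutation of 1..N regardless of input order.
    """
    order = sorted(
        range(len(enhancers)),
        key=lambda i: (
            enhancers[i].signal,
            enhancers[i].interval.chrom,
            enhancers[i].interval.start,
        ),
    )
    cutoff_signal, cutoff_rank = hockey_stick_cutoff(
        [e.signal for e in enhancers]
    )
    for rank0, i in enumerate(order):
        enhancers[i].rank = rank0 + 1
        enhancers[i].is_super = enhancers[i].signal > cutoff_signal
    return cutoff_signal, cutoff_rank


def map_genes(
    enhancers: list[StitchedEnhancer],
    tss_table: TSSTable,
    window: int = DEFAULT_GENE_WINDOW,
    assignment: str = "window",
) -> tuple[list[list[str]], set[str], list[tuple[str, float]]]:
    """Assign genes to enhancers by TSS proximity.

    ``assignment='window'`` (ROSE's proximal rule) assigns every gene whose
    TSS lies inside the enhancer or within ``window`` bp of either boundary;
    ``assignment='overlap'`` requires the TSS inside the interval. Returns
    (per-enhancer gene lists, SE gene set, TE genes ranked by the max signal
    of their best TE ascending, excluding SE genes).
    """
    if len(tss_table) == 0:
        raise ValueError("tss_table must be non-empty")
    if assignment not in {"window", "overlap"}:
        raise ValueError("assignment must be 'window' or 'overlap'")
    pad = window if assignment == "window" else 0
    by_chrom = {}
    for chrom, grp in tss_table.by_chrom().items():
        pos = grp["tss"].to_numpy(np.int64)
        order = np.argsort(pos, kind="stable")
        by_chrom[chrom] = (pos[order], grp.index.to_numpy()[order])

    per_enhancer: list[list[str]] = []
    se_genes: set[str] = set()
    te_best: dict[str, float] = {}
    for e in enhancers:
        entry = by_chrom.get(e.interval.chrom)
        if entry is None:
            per_enhancer.append([])
            continue
        pos, names = entry
        lo = np.searchsorted(pos, e.interval.start - pad, side="left")
        hi = np.searchsorted(pos, e.interval.end - 1 + pad, side="right")
        genes = [str(g) for g in names[lo:hi]]
        per_enhancer.append(genes)
        if e.is_super:
            se_genes.update(genes)
        else:
            for g in genes:
                te_best[g] = max(te_best.get(g, -np.inf), e.signal)
    te_ranked = sorted(
        ((g, s) for g, s in te_best.items() if g not in se_genes),
        key=lambda gs: (gs[1], gs[0]),
    )
    return per_enhancer, se_genes, te_ranked


def build_te_control_signature(
    se_genes: set[str],
    te_genes_ranked: list[tuple[str, float]],
    name: str = "TE_control",
) -> GeneSignature:
    """The bottom-|SE genes| typical-enhancer genes, as a control signature."""
    k = len(se_genes)
    if len(te_genes_ranked) < k:
        logger.warning(
            "only %d TE genes available for a %d-gene control; using all",
            len(te_genes_ranked), k,
        )
        k = len(te_genes_ranked)
    chosen = frozenset(g for g, _ in te_genes_ranked[:k])
    return GeneSignature(
        name=name,
        genes=chosen,
        provenance=f"bottom-{k} TE-associated genes by stitched signal",
    )


@dataclass
class SECallResult:
    """Full output of one sample's super-enhancer call."""

    enhancers: list[StitchedEnhancer]
    cutoff_signal: float
    cutoff_rank: int
    se_genes: set[str]
    te_genes_ranked: list[tuple[str, float]]
    enhancer_genes: list[list[str]] = field(default_factory=list)

    @property
    def n_super(self) -> int:
        return sum(e.is_super for e in self.enhancers)


class SuperEnhancerCaller(BaseEstimator):
    """ROSE-style super-enhancer caller with sklearn estimator semantics.

    Parameters
    ----------
    stitch_distance : int
        Maximum edge-to-edge gap (bp) merged into one stitched region.
    promoter_flank : int
        Half-width (bp) of the promoter window whose peaks are excluded.
    gene_window : int
        TSS proximity (bp) for enhancer-to-gene assignment.
    assignment : {'window', 'overlap'}
        Proximal-window or strict-overlap gene assignment.
    exclude_promoters : bool
        Whether promoter-window constituent peaks are removed before stitching.

    After ``fit(peaks, tss_table=...)`` the fitted attributes are
    ``enhancers_``, ``cutoff_signal_``, ``cutoff_rank_``, ``se_genes_``,
    ``te_genes_ranked_`` and ``result_``.
    """

    def __init__(
        self,
        stitch_distance: int = DEFAULT_STITCH_DISTANCE,
        promoter_flank: int = DEFAULT_PROMOTER_FLANK,
        gene_window: int = DEFAULT_GENE_WINDOW,
        assignment: str = "window",
        exclude_promoters: bool = True,
    ):
        self.stitch_distance = stitch_distance
        self.promoter_flank = promoter_flank
        self.gene_window = gene_window
        self.assignment = assignment
        self.exclude_promoters = exclude_promoters

    def fit(self, peaks: list[Peak], y=None, *, tss_table: TSSTable):
        if self.stitch_distance < 0 or self.promoter_flank < 0 or self.gene_window < 0:
            raise ValueError("distances must be non-negative")
        work = sort_peaks(peaks)
        if self.exclude_promoters:
            work = exclude_promoter_peaks(work, tss_table, flank=self.promoter_flank)
        enhancers = stitch_peaks(work, stitch_distance=self.stitch_distance)
        if len(enhancers) < 2:
            raise ValueError("need at least 2 stitched enhancers to place a cutoff")
        cutoff_signal, cutoff_rank = rank_and_classify(enhancers)
        enhancer_genes, se_genes, te_ranked = map_genes(
            enhancers, tss_table, window=self.gene_window, assignment=self.assignment
        )
        self.enhancers_ = enhancers
        self.cutoff_signal_ = cutoff_signal
        self.cutoff_rank_ = cutoff_rank
        self.se_genes_ = se_genes
        self.te_genes_ranked_ = te_ranked
        self.result_ = SECallResult(
            enhancers=enhancers,
            cutoff_signal=cutoff_signal,
            cutoff_rank=cutoff_rank,
            se_genes=se_genes,
            te_genes_ranked=te_ranked,
            enhancer_genes=enhancer_genes,
        )
        return self

    def te_control_signature(self, name: str = "TE_control") -> GeneSignature:
        return build_te_control_signature(self.se_genes_, self.te_genes_ranked_, name=name)


def call_super_enhancers(
    peaks: list[Peak],
    tss_table: TSSTable,
    stitch_distance: int = DEFAULT_STITCH_DISTANCE,
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
    gene_window: int = DEFAULT_GENE_WINDOW,
    assignment: str = "window",
    exclude_promoters: bool = True,
) -> SECallResult:
    """Functional wrapper over :class:`SuperEnhancerCaller`."""
    caller = SuperEnhancerCaller(
        stitch_distance=stitch_distance,
        promoter_flank=promoter_flank,
        gene_window=gene_window,
        assignment=assignment,
        exclude_promoters=exclude_promoters,
    )
    return caller.fit(peaks, tss_table=tss_table).result_
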