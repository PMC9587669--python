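"""Differential expression, enrichment fractions, GSVA scoring and GSEA.

The differential test is a two-sided Welch t on log2 values with
Benjamini-Hochberg adjustment: the artifact consumes expression matrices
(R2-style microarray summaries or FPKM), not read counts, so a count-based
model is out of scope and externally computed log2FC/FDR columns can be
supplied verbatim wherever a DE table is accepted.

GSVA here is the kernel-CDF / symmetric-rank-statistic single-sample scorer:
per gene a Gaussian kernel CDF (bandwidth sd/4) turns expression into
sample-wise cumulative scores, per sample genes are ranked by that score and
a weighted Kolmogorov-Smirnov-like random walk over the ranking yields one
score per (signature, sample). GSEA is the weighted running-sum statistic
with a gene-label permutation null; with only two samples per treatment arm
a phenotype-permutation null is impossible, so the gene null is the default
and only option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .core import DependencyMatrix, ExpressionMatrix, GeneSignature

logger = logging.getLogger("secircuit")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, order-preserving, idempotent)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential expression

def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b,
    min_mean_expr: float | None = None,
) -> pd.DataFrame:
    """Welch-t differential expression of group_a versus group_b.

    ``group_b`` may be a single label or a list of labels (pooled, e.g. the
    other three subtypes). log2FC = mean_a - mean_b on the log2 scale.
    ``min_mean_expr`` drops genes whose mean expression on the matrix's
    declared scale is below the floor *before* testing, so the BH adjustment
    runs only over actively expressed genes. Returns a DataFrame indexed by
    gene with columns log2fc, p, fdr, mean_a, mean_b, mean_expr.
    """
    groups_b = [group_b] if isinstance(group_b, str) else list(group_b)
    cols_a = matrix.samples_in_group(group_a)
    cols_b = [s for g in groups_b for s in matrix.samples_in_group(g)]
    if len(cols_a) < 2:
        raise ValueError(f"group {group_a!r} has {len(cols_a)} samples; need >= 2")
    if len(cols_b) < 2:
        raise ValueError(f"group(s) {groups_b} have {len(cols_b)} samples; need >= 2")

    values = matrix.values
    if min_mean_expr is not None:
        keep = values[cols_a + cols_b].mean(axis=1) >= min_mean_expr
        values = values[keep]
    log2 = values if matrix.scale == "log2" else np.log2(values + 1.0)

    a = log2[cols_a].to_numpy(float)
    b = log2[cols_b].to_numpy(float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_a - mean_b

    with warnings.catch_warnings():
        # zero-variance rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate rows: both groups zero-variance
    flat = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(flat & (log2fc == 0), 1.0, p)
    p = np.where(flat & (log2fc != 0), 0.0, p)
    p = np.nan_to_num(p, nan=1.0)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "fdr": benjamini_hochberg(p),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "mean_expr": values[cols_a + cols_b].mean(axis=1).to_numpy(float),
        },
        index=values.index,
    )
    return out


def signature_enrichment_fractions(
    de: pd.DataFrame,
    signature: GeneSignature,
    log2fc_cut: float,
    fdr_cut: float = 0.05,
) -> tuple[pd.Series, float]:
    """Per-gene log2FC of the signature plus its significant-up fraction.

    The fraction is (# signature genes with log2fc > cut and fdr < fdr_cut)
    over the signature genes present in the DE table; genes missing from the
    table are dropped (count logged).
    """
    de_upper = de.copy()
    de_upper.index = de_upper.index.astype(str).str.upper()
    present = [g for g in sorted(signature.genes) if g in de_upper.index]
    n_missing = len(signature.genes) - len(present)
    if n_missing:
        logger.info(
            "signature %s: %d of %d genes absent from DE table",
            signature.name, n_missing, len(signature.genes),
        )
    if not present:
        raise ValueError(f"no {signature.name} genes present in the DE table")
    sub = de_upper.loc[present]
    frac = float(((sub["log2fc"] > log2fc_cut) & (sub["fdr"] < fdr_cut)).mean())
    return sub["log2fc"], frac


def dependency_fraction(
    dep: DependencyMatrix,
    signature: GeneSignature,
    ceres_cut: float = -0.1,
) -> pd.Series:
    """Per-cell-line fraction of signature genes with CERES below the cut."""
    present = [g for g in sorted(signature.genes) if g in dep.values.index]
    if not present:
        raise ValueError(f"no {signature.name} genes present in the dependency matrix")
    sub = dep.values.loc[present]
    return (sub < ceres_cut).mean(axis=0)


# ---------------------------------------------------------------------------
# GSVA

def _kernel_cdf_scores(X: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Per-gene Gaussian-kernel cumulative scores (genes x samples).

    z_ij = mean_k Phi((x_ij - x_ik) / h_i) with bandwidth h_i = sd_i / 4;
    constant genes get a flat 0.5. Translation of a gene's row leaves its
    scores unchanged.
    """
    p, n = X.shape
    sd = X.std(axis=1, ddof=1)
    h = sd / 4.0
    Z = np.full((p, n), 0.5)
    ok = h > 0
    idx = np.flatnonzero(ok)
    for lo in range(0, idx.size, chunk):
        rows = idx[lo:lo + chunk]
        diffs = (X[rows, :, None] - X[rows, None, :]) / h[rows, None, None]
        Z[rows] = stats.norm.cdf(diffs).mean(axis=2)
    return Z


def gsva_scores(
    matrix: ExpressionMatrix,
    signatures,
    tau: float = 1.0,
    method: str = "difference",
) -> pd.DataFrame:
    """Single-sample signature scores (signatures x samples).

    ``signatures`` is a dict name -> gene set or an iterable of
    :class:`GeneSignature`. ``method='difference'`` (default) scores each
    walk as its largest positive plus largest negative deviation; 'maxdev'
    uses the classic single maximal deviation. Signatures with fewer than
    two genes present score NaN with a warning. Requires >= 3 samples.
    """
    if isinstance(signatures, dict):
        sig_items = [(k, set(v)) for k, v in signatures.items()]
    else:
        sig_items = [(s.name, set(s.genes)) for s in signatures]
    if method not in {"difference", "maxdev"}:
        raise ValueError("method must be 'difference' or 'maxdev'")
    log2 = matrix.log2()
    values = log2.values.sort_index()  # lexicographic order fixes rank ties
    p, n = values.shape
    if n < 3:
        raise ValueError(f"GSVA requires >= 3 samples, got {n}")
    X = values.to_numpy(float)
    Z = _kernel_cdf_scores(X)

    # per sample: genes ordered by z descending, ties by gene symbol
    order = np.argsort(-Z, axis=0, kind="stable")  # (p, n)
    ranks = np.empty_like(order)
    ar = np.arange(1, p + 1)
    for j in range(n):
        ranks[order[:, j], j] = ar
    rho = np.abs(p / 2.0 - ranks)  # symmetric rank statistic

    gene_pos = {g: i for i, g in enumerate(values.index)}
    out = np.full((len(sig_items), n), np.nan)
    for si, (sig_name, genes) in enumerate(sig_items):
        members = sorted({str(g).upper() for g in genes} & gene_pos.keys())
        if len(members) < 2:
            logger.warning(
                "GSVA: signature %s has %d genes present (< 2); score NaN",
                sig_name, len(members),
            )
            continue
        mask = np.zeros(p, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        k = mask.sum()
        dec = 1.0 / (p - k)
        for j in range(n):
            ord_j = order[:, j]
            m = mask[ord_j]
            w = np.where(m, rho[ord_j, j] ** tau, 0.0)
            total = w.sum()
            steps = np.where(m, w / total, -dec)
            walk = np.cumsum(steps)
            vmax, vmin = walk.max(), walk.min()
            if method == "difference":
                out[si, j] = max(vmax, 0.0) + min(vmin, 0.0)
            else:
                out[si, j] = vmax if vmax >= -vmin else vmin
    return pd.DataFrame(out, index=[s for s, _ in sig_items], columns=values.columns)


class GsvaScorer(BaseEstimator, TransformerMixin):
    """Sklearn transformer turning samples x genes expression into
    samples x signatures GSVA scores.

    Follows the (n_samples, n_features) orientation so it composes with
    sklearn pipelines; :func:`gsva_scores` is the genes x samples functional
    counterpart. ``fit`` records which signature genes are present.
    """

    def __init__(self, signatures=None, tau: float = 1.0, method: str = "difference",
                 scale: str = "log2"):
        self.signatures = signatures
        self.tau = tau
        self.method = method
        self.scale = scale

    def _sig_dict(self) -> dict[str, set[str]]:
        if isinstance(self.signatures, dict):
            return {k: set(v) for k, v in self.signatures.items()}
        return {s.name: set(s.genes) for s in (self.signatures or [])}

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("GsvaScorer requires a DataFrame with gene-named columns")
        if not self._sig_dict():
            raise ValueError("no signatures configured")
        genes = set(g.upper() for g in X.columns.astype(str))
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        self.genes_present_ = {
            name: sorted({str(g).upper() for g in gs} & genes)
            for name, gs in self._sig_dict().items()
        }
        self.signature_names_ = list(self._sig_dict())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "signature_names_"):
            raise ValueError("GsvaScorer is not fitted")
        matrix = ExpressionMatrix(
            values=X.T,
            groups=pd.Series("NA", index=X.index),
            scale=self.scale,
        )
        scores = gsva_scores(matrix, self._sig_dict(), tau=self.tau, method=self.method)
        return scores.T.loc[X.index]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.signature_names_, dtype=object)


# ---------------------------------------------------------------------------
# GSEA

@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's GSEA outcome on one ranking."""

    name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    n_genes: int
    direction: str  # 'up' or 'down'


def _es_from_positions(pos, weights, n_genes, cum=None):
    """Signed extreme of the running sum given sorted hit positions.

    ``pos``/``weights`` are (B, k) arrays of 0-based hit positions (sorted
    ascending per row) and the corresponding |metric|^p weights.
    Returns (B,) signed ES values.
    """
    k = pos.shape[1]
    dec = 1.0 / (n_genes - k)
    cw = np.cumsum(weights, axis=1)
    total = cw[:, -1:].copy()
    total[total == 0] = 1.0  # all-zero-weight rows walk flat between hits
    misses_before = pos - np.arange(k)
    v_after = cw / total - misses_before * dec
    v_before = (cw - weights) / total - misses_before * dec
    es_pos = v_after.max(axis=1)
    es_neg = np.minimum(v_before.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def _prepare_ranking(metric: pd.Series):
    m = metric.copy()
    m.index = m.index.astype(str).str.upper()
    if not np.isfinite(m.to_numpy(float)).all():
        raise ValueError("ranking metric must be finite")
    order = sorted(m.index, key=lambda g: (-m[g], g))
    return m.loc[order]


def gsea_multi(
    metric: pd.Series,
    gene_sets: dict,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, EnrichmentResult]:
    """GSEA of several gene sets against one ranking metric.

    Genes are sorted by metric descending (ties by symbol); the running sum
    adds |metric|^weight_p (normalized over set hits) at hits and subtracts
    1/(N - N_hit) at misses; ES is the signed extreme deviation. The null
    resamples set membership uniformly (gene-label permutation); NES divides
    ES by the mean |null ES| of matching sign, and the FDR is the standard
    sign-stratified ratio of null to observed NES tail fractions.
    """
    ranked = _prepare_ranking(metric)
    n = len(ranked)
    base_w = np.abs(ranked.to_numpy(float)) ** weight_p
    gene_pos = {g: i for i, g in enumerate(ranked.index)}
    rng = np.random.default_rng(seed)

    observed: dict[str, float] = {}
    null_es: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        hits = sorted({gene_pos[str(g).upper()] for g in genes
                       if str(g).upper() in gene_pos})
        if not hits:
            raise ValueError(f"gene set {name!r} has no genes in the ranking")
        if len(hits) >= n:
            raise ValueError(f"gene set {name!r} covers the whole ranking")
        pos = np.asarray(hits)[None, :]
        observed[name] = float(_es_from_positions(pos, base_w[pos], n)[0])
        k = len(hits)
        perm_pos = np.sort(
            rng.permuted(np.broadcast_to(np.arange(n), (n_perm, n)), axis=1)[:, :k],
            axis=1,
        )
        null_es[name] = _es_from_positions(perm_pos, base_w[perm_pos], n)

    def normalize(es: float, null: np.ndarray) -> float:
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.nan
        return es / denom if denom and np.isfinite(denom) else np.nan

    nes_obs = {name: normalize(observed[name], null_es[name]) for name in gene_sets}
    nes_null = {
        name: np.array([normalize(e, null_es[name]) for e in null_es[name]])
        for name in gene_sets
    }
    all_null = np.concatenate(list(nes_null.values()))
    all_obs = np.array(list(nes_obs.values()), dtype=float)

    results: dict[str, EnrichmentResult] = {}
    for name in gene_sets:
        es, nes = observed[name], nes_obs[name]
        null = null_es[name]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        p = (1 + (np.abs(same) >= abs(es)).sum()) / (1 + same.size)
        # sign-stratified FDR over the pooled null NES
        if np.isfinite(nes) and nes != 0:
            null_same = all_null[np.sign(all_null) == np.sign(nes)]
            obs_same = all_obs[np.sign(all_obs) == np.sign(nes)]
            frac_null = ((np.abs(null_same) >= abs(nes)).mean()
                         if null_same.size else 1.0)
            frac_obs = ((np.abs(obs_same) >= abs(nes)).mean()
                        if obs_same.size else 1.0)
            fdr = min(1.0, frac_null / frac_obs) if frac_obs > 0 else 1.0
        else:
            fdr = 1.0
        results[name] = EnrichmentResult(
            name=name,
            es=es,
            nes=float(nes),
            p_perm=float(p),
            fdr=float(fdr),
            n_genes=int(sum(str(g).upper() in gene_pos for g in gene_sets[name])),
            direction="up" if es >= 0 else "down",
        )
    return results


def gsea(
    metric: pd.Series,
    gene_set,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    name: str = "set",
) -> EnrichmentResult:
    """GSEA of one gene set; FDR reduces to the permutation p for a single set."""
    if isinstance(gene_set, GeneSignature):
        name, genes = gene_set.name, set(gene_set.genes)
    else:
        genes = set(gene_set)
    res = gsea_multi(metric, {name: genes}, weight_p=weight_p, n_perm=n_perm, seed=seed)
    return res[name]
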