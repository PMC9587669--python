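"""Seed-reproducible synthetic inputs with the structure the pipeline assumes.

The generators emulate, at desk scale, the data the analysis consumes: one
synthetic chromosome with clustered high-signal H3K27Ac peaks planted near
designated driver genes (recovering them is the SE caller's ground truth), a
tissue-level SE gene list overlapping the drivers, subtype-structured
expression with the drivers upregulated in the G3 arm, CERES-style
dependency scores with the drivers depleting, survival times whose hazard
is tied to a signature score, and median-effect dose-response surfaces with
configurable Loewe interaction.

Every generator draws from its own stream derived from (master seed,
generator name), so outputs are byte-identical across runs and adding a
generator does not shift the others. Ground truth is always returned next
to the data; no analysis stage reads it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import (
    DependencyMatrix,
    ExpressionMatrix,
    GenomicInterval,
    Peak,
    SurvivalTable,
    TSSTable,
)

SUBTYPES = ["G3", "WNT", "SHH", "G4"]

#: background peaks must not be able to stitch: enforced grid clearance (bp)
DEFAULT_STITCH_SAFETY = 12_500


def stream(master_seed: int, name: str) -> np.random.Generator:
    """Independent generator stream keyed by (master seed, generator name)."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([int(master_seed), key])


@dataclass(frozen=True)
class SEClusterSpec:
    """Planted super-enhancer cluster geometry and intensity."""

    peaks_per_cluster: int = 5
    peak_width: int = 1000
    intra_cluster_gap: int = 2000       # must stay below the stitch distance
    density_multiplier: float = 10.0    # x background 90th percentile
    promoter_offset: int = 3500         # cluster start downstream of the TSS


@dataclass(frozen=True)
class ExpressionSpec:
    n_per_group: int = 20
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    planted_log2_shift: float = 2.0     # G3 upshift of planted genes
    noise_sd: float = 1.0
    treatment_log2_shift: float = -2.0  # drug suppression of planted genes
    treatment_noise_sd: float = 0.3
    n_treatment_replicates: int = 2     # per arm, mirroring n = 2 drug RNA-seq


@dataclass(frozen=True)
class DependencySpec:
    dependent_mean: float = -0.6
    dependent_sd: float = 0.15
    neutral_mean: float = 0.0
    neutral_sd: float = 0.1


@dataclass(frozen=True)
class SurvivalSpec:
    baseline_hazard: float = 0.02       # events per month
    beta: float = 0.8                   # log-hazard per SD of score
    censoring_rate: float = 0.3
    n_patients: int = 100


@dataclass(frozen=True)
class DoseResponseSpec:
    m_1: float = 1.5
    dm_1: float = 50.0                  # nM-scale potency, drug 1
    m_2: float = 1.2
    dm_2: float = 500.0                 # drug 2
    n_doses: int = 8
    dose_span: float = 8.0              # single agents span Dm/span .. Dm*span
    noise_sd: float = 0.0
    interaction: str = "loewe-additive"  # or 'synergistic' / 'antagonistic'
    gamma: float = 1.0                  # potency multiplier on required doses
    fa_grid: tuple = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, validated on construction."""

    seed: int = 0
    genome_length: int = 10_000_000
    chrom: str = "chr1"
    n_genes: int = 500
    n_cell_lines: int = 5
    n_planted_se_genes: int = 20
    background_peak_count: int = 300
    background_density_mean: float = 0.3   # rpm/bp, exponential
    background_density_floor: float = 0.01
    background_density_cap_quantile: float = 0.93  # truncates the exponential tail
    background_peak_width: int = 1_000
    input_density_mean: float = 0.03
    min_tss_spacing: int = 2_000
    driver_clearance: int = 150_000        # no other TSS this close to a driver
    background_peak_margin: int = 45_000   # no background peak this close to a driver TSS
    n_tissue_extra_genes: int = 30         # tissue-only genes added to the tSE list
    n_expression_datasets: int = 4
    n_nc_datasets: int = 2                 # how many of those carry NC samples
    stitch_distance: int = 12_500
    cluster: SEClusterSpec = field(default_factory=SEClusterSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    dependency: DependencySpec = field(default_factory=DependencySpec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    dose_response: DoseResponseSpec = field(default_factory=DoseResponseSpec)

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_cell_lines, self.n_planted_se_genes,
                  self.background_peak_count, self.genome_length)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_planted_se_genes >= self.n_genes:
            raise ValueError("planted genes must be a strict subset of all genes")
        if self.cluster.intra_cluster_gap >= self.stitch_distance:
            raise ValueError("intra-cluster gap must be below the stitch distance")
        span = self.cluster_span
        if self.cluster.promoter_offset <= 2_500:
            raise ValueError("cluster must start beyond the 2.5 kb promoter window")
        if 2 * self.driver_clearance * self.n_planted_se_genes > self.genome_length:
            raise ValueError("genome too small for the driver clearance zones")
        if not (np.isfinite(self.survival.baseline_hazard)
                and np.isfinite(self.survival.beta)):
            raise ValueError("survival hazard parameters must be finite")
        if span + self.cluster.promoter_offset >= self.driver_clearance:
            raise ValueError("cluster span exceeds the driver clearance")

    @property
    def cluster_span(self) -> int:
        c = self.cluster
        return (c.peaks_per_cluster * c.peak_width
                + (c.peaks_per_cluster - 1) * c.intra_cluster_gap)

    @property
    def driver_genes(self) -> list[str]:
        return [f"DRV{i:04d}" for i in range(1, self.n_planted_se_genes + 1)]

    @property
    def cell_lines(self) -> list[str]:
        return [f"LINE{i}" for i in range(1, self.n_cell_lines + 1)]


# ---------------------------------------------------------------------------
# annotation

def generate_annotation(config: SimulationConfig) -> TSSTable:
    """Place one TSS per gene on the synthetic chromosome.

    Driver genes sit on an even grid with a guaranteed clearance from every
    other gene, so that a planted enhancer cluster (and its gene-assignment
    window) can only reach its own driver; the remaining genes are
    uniformly spaced with jitter in the leftover space.
    """
    rng = stream(config.seed, "annotation")
    L, k = config.genome_length, config.n_planted_se_genes
    clearance = config.driver_clearance

    step = L / (k + 1)
    jitter = rng.uniform(-0.05 * step, 0.05 * step, size=k)
    driver_pos = np.sort((np.arange(1, k + 1) * step + jitter).astype(np.int64))
    if np.diff(driver_pos).min(initial=L) <= 2 * clearance:
        raise ValueError("driver placement collision: genome too small")

    # leftover segments outside every driver clearance zone
    segments = []
    cursor = 0
    for dp in driver_pos:
        lo, hi = max(0, dp - clearance), min(L, dp + clearance)
        if lo > cursor:
            segments.append((cursor, lo))
        cursor = hi
    if cursor < L:
        segments.append((cursor, L))
    seg_lens = np.array([b - a for a, b in segments], dtype=float)
    total = seg_lens.sum()

    n_bg = config.n_genes - k
    spacing = total / n_bg
    if spacing < config.min_tss_spacing:
        raise ValueError(
            f"genome too small: background TSS spacing {spacing:.0f} bp "
            f"below the {config.min_tss_spacing} bp floor"
        )
    lin = (np.arange(n_bg) + 0.5) * spacing
    lin = lin + rng.uniform(-0.4, 0.4, size=n_bg) * spacing
    offsets = np.concatenate([[0.0], np.cumsum(seg_lens)])
    seg_idx = np.clip(np.searchsorted(offsets, lin, side="right") - 1,
                      0, len(segments) - 1)
    bg_pos = np.array(
        [segments[s][0] + (x - offsets[s]) for s, x in zip(seg_idx, lin)],
        dtype=np.int64,
    )

    genes = config.driver_genes + [f"GENE{i:04d}" for i in range(1, n_bg + 1)]
    pos = np.concatenate([driver_pos, bg_pos])
    strands = rng.choice(["+", "-"], size=config.n_genes)
    frame = pd.DataFrame(
        {"chrom": config.chrom, "tss": pos, "strand": strands}, index=genes
    )
    frame.index.name = "gene"
    return TSSTable(frame)


# ---------------------------------------------------------------------------
# ChIP-seq peaks

def generate_chipseq_samples(
    config: SimulationConfig, annotation: TSSTable
) -> tuple[dict[str, list[Peak]], set[str]]:
    """Per-cell-line peak lists plus the ground-truth SE gene set.

    Background peaks follow a right-skewed (truncated exponential) density
    and sit on a jittered grid whose gaps always exceed the stitch distance,
    so background regions never chain together; they also keep a margin
    around every driver TSS so nothing can stitch onto a planted cluster.
    Planted clusters sit downstream of their driver's TSS, outside the
    +/- 2.5 kb promoter window, with constituent density at
    ``density_multiplier`` times the background 90th percentile. The grid
    spacing and the truncated tail keep the ranked background curve smooth
    at its top, which pins the hockey-stick tangent to the background /
    cluster boundary and makes ground-truth recovery exact.
    """
    missing = [g for g in config.driver_genes if g not in annotation]
    if missing:
        raise ValueError(f"annotation lacks driver genes: {missing[:3]}")
    driver_tss = np.array(
        [annotation.position(g)[1] for g in config.driver_genes], dtype=np.int64
    )
    c = config.cluster
    q90 = config.background_density_mean * np.log(10.0)  # exponential 90th pct

    width = config.background_peak_width
    spacing = config.genome_length / config.background_peak_count
    if 0.5 * spacing - width <= DEFAULT_STITCH_SAFETY:
        raise ValueError(
            "background grid too dense: peaks could stitch across the "
            f"{DEFAULT_STITCH_SAFETY} bp stitch distance"
        )
    cap = -config.background_density_mean * np.log(
        1.0 - config.background_density_cap_quantile
    )

    samples: dict[str, list[Peak]] = {}
    for line in config.cell_lines:
        rng = stream(config.seed, f"chipseq:{line}")
        peaks: list[Peak] = []

        n = config.background_peak_count
        grid = (np.arange(n) + 0.5) * spacing
        starts = (grid + rng.uniform(-0.25, 0.25, size=n) * spacing).astype(np.int64)
        dens = np.clip(
            rng.exponential(config.background_density_mean, size=n),
            config.background_density_floor, cap,
        )
        inputs = rng.exponential(config.input_density_mean, size=n)
        for s, d, inp in zip(starts, dens, inputs):
            e = int(s + width)
            if np.abs(driver_tss - (s + e) / 2).min() < config.background_peak_margin:
                continue
            peaks.append(
                Peak(
                    interval=GenomicInterval(config.chrom, int(s), e),
                    sample_density=float(d),
                    input_density=float(inp),
                    sample_id=line,
                )
            )

        for tss in driver_tss:
            start = int(tss + c.promoter_offset)
            for j in range(c.peaks_per_cluster):
                s = start + j * (c.peak_width + c.intra_cluster_gap)
                dens_j = (c.density_multiplier * q90
                          * float(np.exp(rng.normal(0.0, 0.1))))
                peaks.append(
                    Peak(
                        interval=GenomicInterval(config.chrom, s, s + c.peak_width),
                        sample_density=dens_j,
                        input_density=float(
                            rng.exponential(config.input_density_mean)
                        ),
                        sample_id=line,
                    )
                )
        samples[line] = sorted(peaks, key=Peak.sort_key)
    return samples, set(config.driver_genes)


def generate_tissue_se_list(config: SimulationConfig, annotation: TSSTable) -> set[str]:
    """A tissue-level SE gene list: the drivers plus tissue-only extras."""
    rng = stream(config.seed, "tissue_se")
    background = [g for g in annotation.genes if g not in set(config.driver_genes)]
    extras = rng.choice(
        np.array(sorted(background)),
        size=min(config.n_tissue_extra_genes, len(background)),
        replace=False,
    )
    return set(config.driver_genes) | {str(g) for g in extras}


# ---------------------------------------------------------------------------
# expression

def generate_expression(
    config: SimulationConfig,
    annotation: TSSTable,
    ground_truth: set[str],
    dataset_id: str = "DS1",
    include_nc: bool = True,
) -> ExpressionMatrix:
    """Subtype-labelled log2 expression with planted G3-upregulated genes."""
    spec = config.expression
    if spec.n_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = stream(config.seed, f"expression:{dataset_id}")
    groups = SUBTYPES + (["NC"] if include_nc else [])
    genes = sorted(annotation.genes)
    n = spec.n_per_group * len(groups)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    labels = np.repeat(groups, spec.n_per_group)
    planted = np.array([g in ground_truth for g in genes])
    values[np.ix_(planted, labels == "G3")] += spec.planted_log2_shift

    samples = [f"{dataset_id}_{g}_{i:02d}" for g in groups
               for i in range(1, spec.n_per_group + 1)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(labels, index=samples),
        scale="log2",
    )


def generate_treatment_expression(
    config: SimulationConfig,
    annotation: TSSTable,
    ground_truth: set[str],
    arm_id: str = "drug",
) -> ExpressionMatrix:
    """Paired treated/control design with the planted signature suppressed."""
    spec = config.expression
    rng = stream(config.seed, f"treatment:{arm_id}")
    genes = sorted(annotation.genes)
    reps = spec.n_treatment_replicates
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    values = baseline[:, None] + rng.normal(
        0.0, spec.treatment_noise_sd, size=(len(genes), 2 * reps)
    )
    planted = np.array([g in ground_truth for g in genes])
    values[np.ix_(planted, np.arange(reps))] += spec.treatment_log2_shift
    samples = ([f"{arm_id}_treated_{i}" for i in range(1, reps + 1)]
               + [f"{arm_id}_control_{i}" for i in range(1, reps + 1)])
    labels = ["treated"] * reps + ["control"] * reps
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(labels, index=samples),
        scale="log2",
    )


# ---------------------------------------------------------------------------
# dependency

def generate_dependency(
    config: SimulationConfig, ground_truth: set[str], annotation: TSSTable
) -> DependencyMatrix:
    """CERES-style gene effects: planted genes depleting, the rest neutral."""
    spec = config.dependency
    rng = stream(config.seed, "dependency")
    genes = sorted(annotation.genes)
    planted = np.array([g in ground_truth for g in genes])
    shape = (len(genes), config.n_cell_lines)
    vals = rng.normal(spec.neutral_mean, spec.neutral_sd, size=shape)
    dep = rng.normal(spec.dependent_mean, spec.dependent_sd, size=shape)
    vals[planted] = dep[planted]
    return DependencyMatrix(
        pd.DataFrame(vals, index=genes, columns=config.cell_lines)
    )


# ---------------------------------------------------------------------------
# survival

def _uniform_censor_max(h0: float, rate: float) -> float:
    """Censor-window upper bound giving the target censoring rate at beta=0.

    With T ~ Exp(h0) and C ~ U(0, c), P(C < T) = (1 - e^{-h0 c})/(h0 c).
    """
    if not 0 < rate < 1:
        raise ValueError("censoring rate must be in (0, 1)")
    f = lambda x: (1.0 - np.exp(-x)) / x - rate
    x = brentq(f, 1e-9, 1e6)
    return x / h0


def generate_survival(config: SimulationConfig, scores: pd.Series) -> SurvivalTable:
    """Exponential event times with hazard h0 * exp(beta * standardized score)."""
    spec = config.survival
    rng = stream(config.seed, "survival")
    s = scores.astype(float)
    sd = s.std(ddof=0)
    z = (s - s.mean()) / sd if sd > 0 else s * 0.0
    hazard = spec.baseline_hazard * np.exp(spec.beta * z.to_numpy())
    t_event = rng.exponential(1.0 / hazard)
    c_max = _uniform_censor_max(spec.baseline_hazard, spec.censoring_rate)
    t_censor = rng.uniform(0.0, c_max, size=len(s))
    time = np.maximum(np.minimum(t_event, t_censor), 1e-6)
    event = (t_event <= t_censor).astype(int)
    return SurvivalTable(
        pd.DataFrame(
            {"time": time, "event": event, "score": s.to_numpy()}, index=s.index
        )
    )


# ---------------------------------------------------------------------------
# dose response

def _dx(fa: np.ndarray, m: float, dm: float) -> np.ndarray:
    return dm * (fa / (1.0 - fa)) ** (1.0 / m)


def generate_dose_response(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Single-agent curves plus an equipotent combination grid.

    Single agents follow fa = 1 / (1 + (Dm/D)^m) plus Gaussian noise on
    viability. Combination points are placed on the equipotent ray at each
    target fa with dose_i = (gamma / 2) * Dx_i(fa), so the exact-model CI at
    every grid point equals gamma (1 for 'loewe-additive'; < 1 synergistic,
    > 1 antagonistic).
    """
    spec = config.dose_response
    mode_gamma = {"loewe-additive": 1.0,
                  "synergistic": spec.gamma,
                  "antagonistic": spec.gamma}
    if spec.interaction not in mode_gamma:
        raise ValueError(f"unknown interaction mode {spec.interaction!r}")
    gamma = mode_gamma[spec.interaction]
    if spec.interaction == "synergistic" and gamma >= 1:
        raise ValueError("synergistic mode needs gamma < 1")
    if spec.interaction == "antagonistic" and gamma <= 1:
        raise ValueError("antagonistic mode needs gamma > 1")
    rng = stream(config.seed, "dose_response")

    def single(drug, m, dm):
        doses = dm * np.geomspace(1.0 / spec.dose_span, spec.dose_span, spec.n_doses)
        if (doses <= 0).any():
            raise ValueError("doses must be > 0")
        fa = 1.0 / (1.0 + (dm / doses) ** m)
        viability = np.clip(1.0 - fa + rng.normal(0, spec.noise_sd, fa.size), 0, 1)
        return pd.DataFrame({"drug": drug, "dose": doses, "viability": viability})

    fa_grid = np.asarray(spec.fa_grid, dtype=float)
    d1 = (gamma / 2.0) * _dx(fa_grid, spec.m_1, spec.dm_1)
    d2 = (gamma / 2.0) * _dx(fa_grid, spec.m_2, spec.dm_2)
    viability = np.clip(
        1.0 - fa_grid + rng.normal(0, spec.noise_sd, fa_grid.size), 0, 1
    )
    combo = pd.DataFrame(
        {"drug_1": "drug1", "drug_2": "drug2",
         "dose_1": d1, "dose_2": d2, "viability": viability}
    )
    return {
        "single_drug1": single("drug1", spec.m_1, spec.dm_1),
        "single_drug2": single("drug2", spec.m_2, spec.dm_2),
        "combination": combo,
        "truth": pd.DataFrame({"fa": fa_grid, "ci_true": gamma}),
    }


# ---------------------------------------------------------------------------
# bundle

@dataclass
class SyntheticStudy:
    """Everything one desk-scale run of the study needs, plus ground truth."""

    config: SimulationConfig
    annotation: TSSTable
    chipseq: dict[str, list[Peak]]
    tissue_se_genes: set[str]
    expression: dict[str, ExpressionMatrix]     # dataset id -> matrix
    nc_datasets: list[str]                      # which datasets carry NC arms
    treatment: ExpressionMatrix
    dependency: DependencyMatrix
    dose_response: dict[str, pd.DataFrame]
    ground_truth_se_genes: set[str]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator under the shared seed policy."""
    annotation = generate_annotation(config)
    chipseq, truth = generate_chipseq_samples(config, annotation)
    tissue = generate_tissue_se_list(config, annotation)
    expression: dict[str, ExpressionMatrix] = {}
    nc_datasets: list[str] = []
    for i in range(1, config.n_expression_datasets + 1):
        ds = f"DS{i}"
        include_nc = i <= config.n_nc_datasets
        expression[ds] = generate_expression(
            config, annotation, truth, dataset_id=ds, include_nc=include_nc
        )
        if include_nc:
            nc_datasets.append(ds)
    return SyntheticStudy(
        config=config,
        annotation=annotation,
        chipseq=chipseq,
        tissue_se_genes=tissue,
        expression=expression,
        nc_datasets=nc_datasets,
        treatment=generate_treatment_expression(config, annotation, truth),
        dependency=generate_dependency(config, truth, annotation),
        dose_response=generate_dose_response(config),
        ground_truth_se_genes=truth,
    )
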