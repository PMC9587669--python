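# Methods

This note documents the models and conventions the package implements, the
defaults it ships with, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Super-enhancer calling

Input is one sample's H3K27Ac peak calls with normalized signal densities
(reads per million per base pair, rpm/bp) and an optional matched input
control. All coordinates are 0-based half-open; GTF annotation is converted
on read (TSS = start − 1 on the plus strand, end − 1 on the minus strand,
so promoter windows centre on the true start of transcription).

1. **Promoter exclusion.** A peak is removed iff its midpoint lies within
   ±`flank` (default 2,500 bp, boundary inclusive) of any TSS. The midpoint
   rule is deterministic and independent of peak width; an overlap-fraction
   variant would couple the decision to peak geometry for no analytical
   gain.
2. **Stitching.** Same-chromosome peaks whose edge-to-edge gap is ≤ the
   stitch distance (default 12,500 bp, inclusive) merge transitively. The
   operation is idempotent and independent of input order.
3. **Quantification.** Region signal = Σ over constituent peaks of
   max(0, sample density − input density) × constituent length, in rpm.
   Subtraction is clamped at zero per constituent so that an over-deep
   input cannot produce negative enhancer signal; gaps between
   constituents contribute nothing.
4. **Hockey-stick cutoff.** Signals are sorted ascending (negatives
   clamped to 0) and a line of slope (max − min)/N is slid along the
   curve; the cutoff rank is the tangent point from below — equivalently
   the rank minimizing the number of points on or below the line, computed
   in O(N) as the argmin of the residual `signal_i − slope·i`. Ties
   resolve to the largest rank (conservative: fewest SE calls). Regions
   with signal strictly above the cutoff signal are super-enhancers; a
   flat curve yields zero. The construction is invariant to rescaling the
   signal axis, and the test suite checks it against an O(N²)
   count-below-line scan.
5. **Gene assignment.** A gene is assigned to a region iff its TSS lies
   inside the region or within `window` bp (default 50,000) of either
   boundary — the proximal rule of the rank-ordering method this
   reimplements; a strict-overlap variant is available
   (`assignment="overlap"`). SE genes are the union over SE regions;
   typical-enhancer (TE) genes are ranked by the best signal of their
   assigned TE, ascending, excluding SE genes. The TE control signature is
   the bottom |SE genes| entries of that ranking (all of it, with a
   warning, if shorter).

## Signatures

- **cSE** — genes SE-associated in ≥ `min_lines` (default 3) of the tumor
  cell lines.
- **oSE** — cSE ∩ the tissue-level SE gene list; symbols are
  uppercase-normalized before any set operation (mixed-case drift across
  datasets is otherwise a silent gene-loss bug), and the tissue list is
  taken verbatim (no alias mapping).
- **vSE** — oSE genes passing, with strict inequalities exactly as the
  criteria are stated:
  - *expression*: log2FC > 0.6 and FDR < 0.05 versus normal cerebellum in
    ≥ 1 dataset, **or** log2FC > 0.2 and FDR < 0.05 versus the other
    subtypes in ≥ 3 datasets (the two contrast families joined by OR, and
    reported separately in the evidence table);
  - *dependency*: CERES gene effect < −0.1 in ≥ 2 cell lines. The −0.1
    cutoff (rather than the conventional −0.5) deliberately retains
    moderately depleting lineage oncogenes; it is exposed in
    `VSECriteria`. By default all cell lines present in the dependency
    matrix count; a whitelist restricts to named lines.

  A gene missing from a dataset simply does not count toward that dataset;
  a gene missing from the dependency matrix counts zero dependent lines
  (logged, not an error). The evidence table has one row per oSE gene with
  every per-dataset verdict, so the filter is auditable and the
  monotonicity property (relaxing any threshold never shrinks the set) is
  testable.

## Expression statistics

- **Differential expression** is a two-sided Welch t-test on log2 values
  with Benjamini–Hochberg adjustment (statsmodels). The package consumes
  expression matrices (microarray summaries, FPKM), not read counts, so a
  count-model test is out of scope; externally computed log2FC/FDR columns
  are accepted verbatim wherever a DE table is an input. An optional
  active-expression floor (e.g. mean FPKM ≥ 1) excludes genes *before*
  testing so the BH adjustment runs only over tested genes. Zero-variance,
  equal-mean rows get p = 1 by definition.
- **GSVA scoring**: per gene, a Gaussian kernel CDF
  `z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with bandwidth `h_i = s_i/4`
  (constant genes score 0.5; the statistic is translation-invariant per
  gene); per sample, genes are ranked by z descending (ties broken by
  gene symbol for determinism) and given the symmetric rank statistic
  `ρ = |p/2 − rank|`; a walk over the ranking adds `ρ^τ` (τ = 1,
  normalized over set members) at in-set genes and subtracts 1/(p − |G|)
  otherwise. The default score is the magnitude-difference convention
  (largest positive plus largest negative deviation, the cited method's
  default); the classic single-max-deviation is available via
  `method="maxdev"`. Signatures with < 2 genes present score NaN with a
  warning; ≥ 3 samples are required.
- **GSEA**: genes sorted by the metric descending; the running sum adds
  `|metric|^p` (p = 1, normalized over set hits) at hits and subtracts
  1/(N − N_hit) at misses; ES is the signed extreme. The null permutes
  gene labels (set membership resampled at fixed size) — the drug
  comparisons this serves have two samples per arm, where a phenotype
  permutation null does not exist. NES divides ES by the mean |null ES|
  of matching sign; the FDR is the standard sign-stratified ratio of null
  to observed NES tail fractions (for a single set it reduces to the
  permutation p). All permutation work is vectorized and seeded.

## Survival

Kaplan–Meier estimation and the two-group Mantel–Cox log-rank test are
delegated to lifelines; subjects censored at an event time remain in the
risk set at that time. Stratification is at the median of the score with
ties assigned to the low group — a fixed convention is required for
determinism and the sign of the choice is conservative for the high-risk
group. A k-group extension is out of scope (every comparison served here
is two-arm).

## Synergy

The median-effect model `fa/(1−fa) = (D/Dm)^m` is fitted by least squares
of log10(fa/(1−fa)) on log10(D) after fa = 1 − viability, clipping fa to
[ε, 1−ε] with ε = 0.005 and discarding non-informative points (fa outside
the open interval) — the inclusion rule is configurable because published
point-selection conventions vary. The combination index is the two-term
(mutually exclusive) form `CI = d₁/Dx₁(fa) + d₂/Dx₂(fa)` with
`Dx(fa) = Dm (fa/(1−fa))^{1/m}`; the three-term conservative variant adds
the cross term via `conservative=True`. CI is invariant under a common
rescaling of one drug's dose units. Viability must be normalized to the
untreated control by the caller.

## Synthetic data

Every generator is a pure function of (config, master seed); each draws
from its own stream keyed by (seed, generator name), so adding a generator
never shifts another's output, and runs are byte-identical under a fixed
seed. Ground truth is returned next to the data and no analysis stage
reads it.

Defaults (one 10 Mb chromosome, 500 genes, 5 cell lines, 20 planted
driver genes, 300 background peaks per line):

- **Annotation.** Driver TSSs sit on an even grid with a guaranteed
  150 kb clearance from every other gene; the remaining genes are placed
  uniformly with jitter in the leftover space (≥ 2 kb apart). The
  clearance is what makes exact recovery well-defined: with a 50 kb
  assignment window, a planted cluster in a uniformly 20 kb-spaced gene
  field would unavoidably capture non-planted neighbours.
- **ChIP-seq.** Background peaks (1 kb wide) sit on a jittered grid whose
  gaps always exceed the stitch distance, with densities from an
  exponential (mean 0.3 rpm/bp, floor 0.01) truncated at its 93rd
  percentile; they keep a 45 kb margin from driver TSSs. Planted clusters
  are 5 peaks × 1 kb with 2 kb gaps starting 3.5 kb downstream of the
  driver TSS (outside the promoter window), at 10× the background 90th
  percentile with mild log-normal jitter. The grid spacing and truncated
  tail keep the ranked background curve smooth at its top; an untruncated,
  clumped background occasionally throws a stitched background chain above
  the tangent point, which is realistic biology but makes exact
  ground-truth recovery an impossible target. Real enhancer landscapes are
  clustered, copy-number confounded and far heavier-tailed than this —
  passing recovery tests here demonstrates correctness of the ranking
  machinery, not calling performance on real chromatin.
- **Expression.** Log2-scale values, Gaussian noise (sd 1.0), baseline
  N(7, 1.5), 20 samples per group across G3/WNT/SHH/G4 (+ NC in 2 of 4
  datasets, mirroring a 4-dataset design where two carry normal
  cerebellum); planted genes are shifted +2.0 in G3. The drug-treatment
  design has 2 replicates per arm (matching the n = 2 RNA-seq the GSEA
  stage serves), noise sd 0.3, planted genes shifted −2.0 under
  treatment.
- **Dependency.** Planted genes ~ N(−0.6, 0.15), others ~ N(0, 0.1) per
  line. At these settings a planted gene is called dependent
  (score < −0.1 in ≥ 2 of 5 lines) with probability ≈ 1 − 10⁻⁵, while a
  neutral gene is miscalled at ≈ 0.18 (the closed-form
  Binomial(5, Φ(−1)) tail — the tests pin the empirical rate to this
  value). The vSE filter still recovers exactly the planted set because
  neutral genes fail the expression arm.
- **Survival.** Event times ~ Exp(h₀ · exp(β·z)) with h₀ = 0.02/month and
  β = 0.8 per SD of score; independent Uniform(0, c) censoring with c
  solved so the censoring fraction is 0.30 at β = 0.
- **Dose-response.** Single agents follow the median-effect curve
  (m = 1.5/1.2, Dm = 50/500 in the two drugs' own units) over 8 doses
  spanning Dm/8..8Dm. Combination points sit on the equipotent ray with
  dose_i = (γ/2)·Dx_i(fa) at each target fa, so the exact-model CI at
  every point equals γ (1 for Loewe-additive; the synergistic and
  antagonistic modes scale the required doses by γ < 1 or γ > 1).

## Numerical conventions

- fa clipping ε = 0.005 before the logit transform; BH adjustment via the
  standard step-up; GSVA/GSEA rank ties broken lexicographically by gene
  symbol; the hockey-stick tie-break takes the largest rank; hazard and
  threshold parameters are validated finite.
- The brute-force hockey-stick oracle used in tests evaluates the tangent
  line with a 1e-9 relative tolerance — at the tangent point the exact
  float comparison can miss its own line by one ULP.

## Problem sizes

The shipped defaults (10 Mb genome, 500 genes, 5 × ~320 peaks, 4
expression datasets at 80–100 samples, 100–500 replicate calibrations)
were chosen so the full test suite and the acceptance script each complete
in well under a coffee break on one CPU while every statistical check
retains comfortable power; all sizes scale up through `SimulationConfig`.

## Known limitations

- The DE test is a Welch t on summarized expression; count-level dispersion
  modelling (as a count-based package would do on raw RNA-seq) is out of
  scope by design.
- GSEA FDR for a single queried set reduces to the permutation p; the
  sign-stratified multi-set FDR needs several sets to be informative.
- The SE caller assumes densities are already depth-normalized (rpm/bp);
  no copy-number correction is attempted.
- The generator does not emulate read-level artifacts (FASTQ), fragment
  size, clustered background enhancers, batch effects across expression
  datasets, or dependency screens' copy-number confounding.
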