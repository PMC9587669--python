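# secircuit

Integrative super-enhancer (SE) dependency analysis for Group 3
medulloblastoma (G3-MB), packaged as a tested, reusable pipeline with a
seed-reproducible synthetic-data generator in place of the study's raw
ChIP-seq, transcriptome, DepMap and viability downloads.

G3-MB is the medulloblastoma subtype with the worst prognosis. Large
clusters of H3K27Ac-marked enhancers — super-enhancers — drive the
transcription of its identity genes, oncogenes and tumor-dependent genes.
This package reimplements the computational chain that goes from raw
H3K27Ac peak calls to a ranked list of SE-driven, subtype-specific,
tumor-dependent candidate target genes, and to the statistics used to
evaluate them:

- **SE calling** (ROSE-style): peaks within ±2.5 kb of a TSS are removed,
  remaining peaks within 12.5 kb of each other are stitched, each stitched
  region is scored by background-subtracted signal
  `Σ max(0, ρ_sample − ρ_input) · length` (rpm), regions are ranked by
  signal and split at the hockey-stick tangent: the rank where a line of
  slope `(max − min)/N` touches the ranked curve from below. Genes are
  assigned by TSS proximity (50 kb window by default).
- **Signatures**: cSE = SE genes recurrent in ≥ 3 cell lines; oSE = cSE ∩
  tissue SE genes; vSE = oSE genes that are upregulated in G3 versus
  normal cerebellum (log2FC > 0.6, FDR < 0.05, ≥ 1 dataset) or versus the
  other subtypes (log2FC > 0.2, FDR < 0.05, ≥ 3 datasets) **and**
  tumor-dependent (CERES gene effect < −0.1 in ≥ 2 cell lines).
- **Expression statistics**: Welch-t differential expression with
  Benjamini–Hochberg adjustment, signature enrichment fractions, GSVA
  single-sample scoring (Gaussian kernel CDF, bandwidth s/4, symmetric
  rank statistic, weighted KS walk), and GSEA with a gene-label
  permutation null (`NES = ES / mean |null ES| of matching sign`).
- **Survival**: Kaplan–Meier estimation and the Mantel–Cox log-rank test
  (via lifelines) on a median split of a signature score.
- **Synergy**: Chou–Talalay median-effect fits
  `fa/(1−fa) = (D/Dm)^m` and the two-term combination index
  `CI = d₁/Dx₁(fa) + d₂/Dx₂(fa)` (CI < 1 synergy, 1 additivity, > 1
  antagonism).

The core computations are exposed as sklearn-style estimators
(`SuperEnhancerCaller`, `GsvaScorer`, `MedianEffectModel`) with functional
wrappers, so they compose with sklearn pipelines and model selection.

## Worked example

```python
from secircuit import SuperEnhancerCaller, SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=1))
caller = SuperEnhancerCaller().fit(study.chipseq["LINE1"],
                                   tss_table=study.annotation)
print(len(caller.enhancers_), caller.result_.n_super,
      round(caller.cutoff_signal_, 1))
print(sorted(caller.se_genes_)[:3])
print(caller.se_genes_ == study.ground_truth_se_genes)
```

prints

```
190 20 796.9
['DRV0001', 'DRV0002', 'DRV0003']
True
```

i.e. 190 stitched enhancer regions, of which the 20 above the
hockey-stick cutoff (796.9 rpm) are super-enhancers, and their assigned
genes are exactly the 20 planted driver genes.

The same study drives the whole pipeline from one config:

```bash
secircuit run --config pipeline.yaml     # or: secircuit simulate / call-se /
                                         # signatures / gsva / gsea / survival / synergy
```

with a `pipeline.yaml` as small as

```yaml
seed: 1
outdir: out
```

The run writes ROSE-style enhancer tables, SE BED files, signature GMTs,
the vSE evidence table, GSVA scores, survival test results, GSEA results,
median-effect fits and per-point combination indices, plus a
`manifest.json` with a checksum per artifact; re-running with the same
seed reproduces every checksum.

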