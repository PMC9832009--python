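# dnbtrack

Tipping-point analysis of temporal transcriptomics with dynamic network
biomarkers (DNB), built around the adeno-to-squamous transdifferentiation
(AST) problem in lung cancer: *Kras*/*Lkb1*-mutant lung adenocarcinomas
(ADC) can abruptly convert into squamous cell carcinomas (SCC), and the
conversion behaves like a critical state transition — gradual drift, then a
sudden, hard-to-reverse switch. `dnbtrack` detects the tipping point of
such a transition from a replicated multi-week RNA-seq series, scores
tumors along the ADC→SCC axis, and tests whether the two lineage
transcription-factor programs mutually suppress each other.

It is aimed at computational biologists analyzing time-course bulk RNA-seq
of state transitions (transdifferentiation, differentiation, treatment
resistance), and ships a synthetic-data generator that plants a critical
transition so every stage can be validated without external data.

## The statistics at the core

**Dynamic network biomarker / composite criticality index.** Approaching a
critical transition, a group of genes (the DNB module) emerges whose
within-group Pearson correlation (PCCᵢ) rises, whose correlation to genes
outside the group (PCCₒ) falls, and whose standard deviation across
replicates (SDᵢ) inflates. Per time point, `dnbtrack` builds the gene–gene
correlation network across replicates inside a lineage-differential
candidate subspace, enumerates candidate modules from an average-linkage
dendrogram on distance 1 − |PCC|, and scores each module with

    CI = (PCCᵢ / PCCₒ) · SDᵢ

The maximum-CI module is the dominant group; the time point where its CI
peaks is the estimated tipping point. A sliding-window variant pools
consecutive time points when replicates are too few for per-timepoint
correlation.

**Lineage signatures and the AST score.** Gene-set signatures use the
combined-z method (per-gene z-standardization across samples, summed and
divided by √k). Lineage component scores are plain means of standardized
expression over genes upregulated in ADC or SCC, and

    AST score = SCC score − ADC score

orders tumors from ADC-like to SCC-like.

**Mutual-suppression ("Yin-Yang") TF network.** One-sided Fisher-exact /
hypergeometric tests of the overlap between TF target sets (e.g. NKX2-1,
FOXA2 for ADC; TP63, SOX2 for SCC) and direction-resolved differential
genes, with Benjamini–Hochberg adjustment; a mutual-suppression verdict
requires both cross-family enrichments to be significant.

## Worked example

```python
import numpy as np
import dnbtrack as dt
from dnbtrack.signatures import lineage_subspace

# 1. simulate a 7-time-point series with a critical transition at 7 weeks
cfg = dt.SyntheticConfig(seed=3)
counts, design, truth = dt.generate_timecourse(cfg)
expr = dt.normalize_rle(counts)            # RLE size factors, log2(RPM + 1)

# 2. lineage-differential candidate subspace from an independent cohort
fractions = np.array([0.0] * 30 + [1.0] * 30)
cohort, _ = dt.generate_adsc_cohort(60, fractions, cfg)
subspace = lineage_subspace(cohort, cohort.sample_ids[:30], cohort.sample_ids[30:])
subspace = [g for g in subspace if g in set(expr.gene_ids)]

# 3. composite-index scan for the tipping point
profile = dt.dnb_scan(expr, design, subspace=subspace)
print(profile.to_frame().round(3).to_string(index=False))
```

prints

```
 time_weeks  pcc_in  pcc_out  sd_in     ci  module_size  is_tipping_point
          0   0.840    0.388  1.326  2.869            6             False
          4   0.850    0.372  1.370  3.129            7             False
          6   0.815    0.339  1.200  2.886            5             False
          7   0.908    0.334  4.019 10.924           31              True
          8   0.817    0.345  1.251  2.963            5             False
          9   0.802    0.329  1.190  2.897            6             False
         10   0.862    0.353  1.616  3.948            5             False
```

The CI of the dominant module spikes at 7 weeks — the planted tipping
point — driven by the simultaneous correlation rise (PCCᵢ 0.91), outside
correlation drop (PCCₒ 0.33) and SD inflation (SDᵢ 4.0). The 31-gene
dominant module contains 30 of the 30 planted DNB genes. Off-transition
time points show the baseline behavior of max-CI selection over noisy
6-replicate correlation estimates (small spurious modules with CI ≈ 3).

The same analysis is available from the shell:

```bash
dnbtrack run --seed 3 --out results/demo          # full pipeline + manifest
dnbtrack cohort --table cohort.csv                # incidence worked examples
```

with subcommands `simulate`, `normalize`, `trajectory`, `dnb`, `score`,
`network`, `cohort` and `run`.

## Layout

- `dnbtrack.io` — counts/design/GMT/TF-map readers, RLE normalization
- `dnbtrack.simulate` — planted-transition and AdSCC-cohort generators
- `dnbtrack.dnb` — correlation networks, module detection, CI, scans
- `dnbtrack.trajectory` — PCA trajectory, marker overlays, dispersion
- `dnbtrack.signatures` — combined-z signatures, differential sets, AST
- `dnbtrack.tfnet` — overlap tests, TF enrichment, Yin-Yang network
- `dnbtrack.cohort`, `dnbtrack.pipeline`, `dnbtrack.cli` — incidence
  tables, orchestration, command line

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
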