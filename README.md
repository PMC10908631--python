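# spatialtme

Spatial single-cell analysis of multiplexed tumor-tissue images — built for
studying how a treatment (here: local tumor irradiation) reorganizes the
cellular architecture of the tumor microenvironment.

Given per-cell tables (centroid, area, marker intensities for a 19-antigen
panel) and per-sample metadata from a two-arm mouse experiment —
non-treated (**NT**) vs irradiated (**IT**) tumors — the package:

1. assigns cell types (neutrophil, other myeloid, CD4 T, CD8 T, tumor) by
   marker gating plus a probabilistic classifier with a low-confidence
   fallback to tumor;
2. builds per-sample spatial interaction graphs over cell centroids
   (expansion radius 15 µm, or 10 nearest neighbors);
3. computes each cell's neighbor-composition profile and clusters the
   pooled profiles with k-means (k = 8) into **cellular neighborhoods**
   (CNs) — groups of cells living in similar local cell-type environments;
4. counts cell-type pair interactions (graph edges) per sample;
5. summarizes **mean signal intensity** (MSI) per cell and for the
   intercellular "cell 0" region from label masks and channel images;
6. compares groups with an unpaired t-test, two-way ANOVA, Pearson
   correlation, the tissue neutrophil-to-lymphocyte ratio
   (tNLR = neutrophils / (CD4 T + CD8 T)), and Kaplan–Meier / log-rank
   survival analysis.

Because studies of this kind rarely deposit per-cell data, the package
includes a first-class synthetic cohort generator that plants the expected
effects — clustered neutrophil infiltrates in NT (a Thomas-type cluster
process), E-Cadherin suppression in NT, correlated survival and serum
NET (NE-DNA) readouts — with full ground truth retained, so every stage of
the pipeline is verifiable. See `docs/methods.md` for models, defaults and
numerical conventions.

## Worked example

```python
from spatialtme import GeneratorConfig, simulate_cohort
from spatialtme.pipeline import analyze_cohort, cohort_statistics

cohort = simulate_cohort(GeneratorConfig(), n_per_group=3, seed=42)
analysis = analyze_cohort(cohort, seed=1)

print(analysis.type_freqs.round(3))
cn = analysis.neutrophil_rich_cn()
print(f"neutrophil-rich CN: {cn}")
print(analysis.cn_freqs[cn].round(3))
report = cohort_statistics(analysis)
print(report["tests"].head(8).round(4).to_string(index=False))
```

prints

```
final_label   cd4t   cd8t  myeloid  neutrophil  tumor
sample_id
IT_1         0.044  0.045    0.152       0.055  0.703
IT_2         0.053  0.042    0.139       0.068  0.698
IT_3         0.038  0.043    0.144       0.061  0.714
NT_1         0.047  0.040    0.124       0.191  0.599
NT_2         0.037  0.026    0.115       0.187  0.635
NT_3         0.027  0.038    0.105       0.176  0.655

neutrophil-rich CN: 3
IT_1    0.044   IT_2    0.062   IT_3    0.046
NT_1    0.180   NT_2    0.181   NT_3    0.171

              test            comparison  statistic  pvalue stars
  t_test_frequency                  cd4t     1.0905  0.3426    ns
  t_test_frequency                  cd8t     2.0020  0.1749    ns
  t_test_frequency               myeloid     4.5480  0.0130     *
  t_test_frequency            neutrophil   -21.1005  0.0000   ***
  t_test_frequency                 tumor     4.4159  0.0357     *
       t_test_tnlr                  tnlr    -8.5232  0.0111     *
t_test_interaction neutrophil-neutrophil    -5.3228  0.0244     *
t_test_interaction      neutrophil-tumor   -12.5586  0.0004   ***
```

Read-out: neutrophils make up ≈ 18 % of cells in untreated samples versus
≈ 6 % after irradiation (t-test, p < 0.001; group order in the test is
IT − NT, hence the negative statistic), one of the eight CNs is
neutrophil-dominated and ≈ 4× more frequent in NT, and NT samples show
more neutrophil–neutrophil and neutrophil–tumor contacts — the planted
spatial reorganization, recovered end to end from the cell table alone.

## Command line

```bash
spatialtme run-all --seed 0 --outdir run0         # full pipeline
spatialtme simulate --seed 0 --outdir sim0        # or stage by stage:
spatialtme gate --cells sim0/cells.csv --outdir gated0
spatialtme graph --cells sim0/cells.csv --graph-method expansion --outdir edges0
```

Each stage reads and writes CSV/TIFF files, so any stage can be re-run
standalone. `run-all` writes cell tables with labels and CN assignments,
edge lists, CN z-score and frequency matrices, interaction and MSI tables,
a tidy statistics report, Kaplan–Meier curves, and a provenance manifest;
re-running with the same config and seed reproduces every CSV bit-exactly.

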