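# mxifhet

Single-cell heterogeneity analysis of multiplexed-immunofluorescence (MxIF)
breast-cancer tissue-microarray (TMA) data.

## The problem

Clinical breast-cancer subtyping (the St. Gallen IHC surrogates: Luminal
A-like, Luminal B-like ± HER2, HER2+ non-luminal, TNBC) scores a whole tumor
core with one label, but MxIF imaging quantifies ER, PR, HER2, Ki67, P53, P21,
P16, CD8 and CD20 in every segmented cell. `mxifhet` turns a per-cell
quantification table into cell-level phenotypes and core-level heterogeneity
statistics:

- **Marker normalization and positivity.** Each marker's compartment-resolved
  raw signal is min-max normalized to 0–15 over all QC-passing cells of the
  dataset, and a cell is called positive when its normalized signal exceeds an
  IHC-calibrated cut-point (ER 0.4, PR 1.6, HER2 5.0, Ki67 0.2, P53 > 0,
  P16 2, P21 1, CD8/CD20 0.2).
- **EPH co-expression classes.** Thresholded (ER, PR, HER2) triplets define 8
  EPH groups — group = 1 + 4·[ERm/s] + 2·[PR+] + [HER2+] — and crossing with
  Ki67 gives 16 classes: class = 2·(group−1) + 1 + [Ki67+].
- **Cancer-population gating.** QC and size gates (perimeter > 90 px, cell
  area > 400 px, nuclear area > 10 px), pan-cytokeratin gating (raw PCK ≥ 1500)
  for luminal/HER2 cores, polygon annotations (benign-duct exclusion, TNBC
  tumor inclusion) for the rest.
- **Spatial neighborhoods.** For every cell, neighbor composition within 30 µm
  (100 px) or 100 µm (341 px), and the Shannon equitability of its
  neighborhood, E_H = H / ln S with H = −Σ pᵢ ln pᵢ — 1 when all in-scope
  species are equally abundant, 0 for a single species. Cumulative
  central-class × neighbor-class co-occurrence matrices and CD8/CD20
  immune-neighborhood profiles use the same machinery.
- **Paired-core heterogeneity.** The two cores of one specimen are compared on
  their 16-class label vectors; a pair is "different" only when both a
  tie-corrected Wilcoxon rank-sum test and a label-permutation test of
  |mean(a) − mean(b)| give p < 0.01. Subtype-level contrasts use one-way ANOVA
  with Tukey HSD.

A fully ground-truthed **synthetic TMA generator** (class-conditional
intensities, uniform or Thomas-cluster point patterns, paired cores, immune
infiltrates, annotations) stands in for real data and backs every test.

## Worked example

```python
from mxifhet.pipeline import RunConfig, run_all

cfg = RunConfig(scenario="default", seed=17, n_cells=1200, n_perm=2000,
                outdir="demo_out")
res = run_all(cfg)
print(f"gated cancer cells: {len(res.cancer_cells)}")
print(res.subtype_tally.to_string(index=False))
print(res.paired_screen.results[0].summary())
```

prints

```
gated cancer cells: 20750
     subtype  n_significant  n_cases  fraction_significant
        HER2              0        2              0.000000
        LumA              1        3              0.333333
        LumB              0        3              0.000000
LumB_HER2pos              0        1              0.000000
        TNBC              0        2              0.000000
case case_001: cores spot_001a (n=969) vs spot_001b (n=960); Wilcoxon p=4.486e-55, permutation p=0.0004998 (n_perm=2000); DIFFERENT at alpha=0.01
```

The default scenario simulates 22 cores (11 paired cases) of 1200 cells; of
26,400 simulated cells, 20,750 survive QC, size and cancer gating. The one
pair flagged as significantly different is `case_001`, into whose second core
the generator deliberately shifted 30% of class mass — the paired Wilcoxon +
permutation screen recovers exactly that planted heterogeneity. The scenario's
HER2+ cores are simulated immune-rich and come out with mean CD8/CD20
densities of 6.95% / 4.97% of all cells versus ~2% / ~1.5% elsewhere.

The same stages are available from the shell:

```sh
mxifhet simulate --scenario default --seed 17 --out sim/
mxifhet preprocess --cells sim/cells.csv --meta sim/cores.csv \
        --annotations sim/regions.geojson --out gated.csv
mxifhet classify --cells gated.csv --out classified.csv
mxifhet spatial --cells classified.csv --radius-um 30 --out profiles.csv
mxifhet stats paired --cells classified.csv --meta sim/cores.csv --out paired.csv
```

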