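# gliamap

Quantification pipeline for white-matter microglia phenotypes, in three
analysis tracks plus a ground-truthed simulator:

- **Morphometrics** (`gliamap.morphometrics`): per-cell feret axis and
  tract-alignment offset (axial angles, capped at 90°), corrected total cell
  fluorescence (integrated density − background × area), density per mm²,
  circularity (4πA/P²), intensity normalization and marker positivity calls,
  colocalization fractions.
- **Spatial statistics** (`gliamap.spatialstats`): reference-derived
  thresholds (mean + k·SD), two-sample KS with exact small-sample p-values,
  point-to-polyline distances with signed midline offsets, a PCA composite
  phenotyping index over per-mouse features, ANOVA + vs-reference
  comparisons, ECDF/histogram reports.
- **Spatial transcriptomics** (`gliamap.transcriptomics`): per-cell QC
  (< 20 transcripts excluded), total-count normalization + log1p z-scaling,
  Pearson-residual HVG selection, PCA/kNN, Leiden clustering
  (resolution 0.1, 1000-iteration budget, seeded), microglia marker gating,
  macrophage gene-matrix exclusion, raw-count enrichment classes (≥ 2
  transcripts, single-gene or gene-set mode), Wilcoxon rank-sum DE with
  exact small-sample enumeration and BH adjustment, Gini marker scores,
  subclustering.
- **Bulk expression** (`gliamap.bulk`): 2^−ΔΔCt relative expression against a
  housekeeper and reference group (per sex when present), negative-probe LOQ
  (geometric mean × geometric SD², log2 space), 15 %-prevalence gene filter
  (boundary inclusive), third-quartile normalization, rank-sum DE for AOI
  contrasts.
- **Synthetic data** (`gliamap.synthetic`): Poisson-placed cells in region
  polygons with group-dependent density/size/shape/tract alignment, planted
  GAL3⁺/APOE⁺ subpopulations with fimbria lateralization, and
  negative-binomial spatial count matrices with planted cell-type signatures
  and log2 fold-changes — every downstream stage is testable against ground
  truth.

Data interchange is plain text: CSV tables, MatrixMarket counts with
`genes.csv`/`cells.csv` sidecars (or long CSV), JSON geometry. Coordinates
are µm, image convention (origin top-left, y downward). See
`DATA_DICTIONARY.md` written into every run directory.

## CLI

```sh
gliamap simulate-section --seed 1 --groups YNG,OLD --mice-per-group 3 --out run/
gliamap morpho --cells run/cells.csv --tracts run/tracts.csv \
    --reference-group YNG --out run/morphometrics.csv
gliamap stratify --run-dir run/ --reference-group YNG
gliamap simulate-counts --seed 1 --scene run/scene.json --out run/counts/
gliamap cluster --counts run/counts/counts.mtx --out run/clusters.csv
gliamap enrich --counts run/counts/counts.mtx --gene Lgals3 --out run/enrich.csv
gliamap de --counts run/counts/counts.mtx --groups groups.csv --out run/de.csv
gliamap geomx --counts aoi_counts.csv --out geomx_out/
gliamap qpcr --ct qpcr.csv --reference-group YNG --out re.csv
gliamap run --seed 1 --out run/      # full pipeline + checksummed manifest
gliamap report --run-dir run/        # markdown summary with figures
```

`gliamap run` executes simulate-section → morpho → stratify →
simulate-counts → cluster → enrich → de and writes `manifest.json` with the
config hash and per-file SHA-256 checksums; reruns with the same config are
byte-identical. Configs are JSON (`RunConfig`), unknown keys are rejected.

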