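# epitrack

Quantitative workflow for bait-interactome screening and membrane-trafficking
assays, built around the cell-biology question of how a surface protein such
as EpCAM is removed from (and returned to) the plasma membrane. It is aimed
at proteomics and cell-biology analysts who have protein-level SILAC
quantifications, STRING-style interaction edge lists, term annotations,
two-channel vesicle images, flow-cytometry event tables from an
antibody-quench internalization assay, and qPCR Ct tables — and want one
tested, reproducible pipeline from those inputs to interactor lists,
interaction clusters, enriched terms, colocalization coefficients, and
endocytosis/recycling rates.

## What it computes

* **SILAC screen** — per-protein enrichment from replicate heavy/light (H/L)
  intensity ratios: mean ratio, t-test p value (two-sided unpaired on log
  intensities, or one-tailed on log2 ratios), optional permutation or
  Benjamini–Hochberg FDR, and the selection filter *mean H/L > 3, p ≤ 0.05,
  ≥ 2 unique peptides*. A transcription of the published 78-protein
  EpCAM-YFP interactor table ships as a fixture.
* **Interactome clustering** — Girvan–Newman divisive clustering: repeatedly
  remove the edge of maximal shortest-path betweenness and keep the partition
  maximizing modularity Q = Σ_c [e_c/m − (d_c/2m)²]; deterministic
  lexicographic tie-breaking.
* **Term enrichment** — one-sided Fisher's exact test
  p = P(X ≥ k), X ~ Hypergeom(N, K, n), against an explicit background, BH
  correction within each namespace (BP/CC/MF/KEGG), chord-diagram export.
* **Colocalization** — threshold-Manders coefficients
  M1 = Σ_{A>t_A} A·[B>t_B]/Σ_{A>t_A} A (and symmetrically M2) with manual
  thresholds.
* **Trafficking assay** — from five gated flow-cytometry groups (unstained,
  100 % labeled, quench background, endocytosis, recycling), the MFI chain
  net(g) = MFI(g) − MFI(quench_bg) after unstained normalization, then
  endocytosis = net(endo)/net(100 %) and recycling =
  (net(endo) − net(rec))/net(endo), with delta-method standard errors, both
  sign conventions, and a timecourse plateau detector.
* **qPCR** — ΔΔCt relative quantification, RQ = 2^(−ΔΔCt), housekeeping-gene
  normalized.
* **Synthetic data** — seeded generators with planted ground truth for every
  stage (interactor screens, flow panels, timecourses, spot-image pairs, Ct
  tables), so the whole pipeline is testable without any downloads.

## Worked example

Select interactors from the packaged published table, then simulate an
antibody-quench assay at the teratoma-cell operating point (8.25 % of surface
label endocytosed, 59.93 % of the internalized pool recycled) and estimate
the rates back:

```sh
$ epitrack screen select --out interactors.tsv
78 protein(s) pass the filter; table written to interactors.tsv

$ epitrack simulate flow --seed 7 --n-cells 10000 --quench-eff 1.0 \
    --endo-frac 0.0825 --recycle-frac 0.5993 --out-dir .
wrote 50000 events to ./flow_events.csv

$ epitrack assay rates --events flow_events.csv
endocytosis: 8.26%  recycling (positive): 59.95%
note: recycling sign convention: positive_recycling = -(as_printed); the as-printed formula is negative for true recycling
```

The 78 selected proteins are every row of the published table (including the
bait, which tops the list at a mean H/L ratio of 61.49, p = 0.018); the
estimated endocytosis and recycling rates recover the planted 8.25 % and
59.93 % to within Monte-Carlo error, and the note flags that the
widely-printed recycling formula has the opposite sign of the reported
quantity.

The same stages are importable as a library
(`epitrack.silac_screen.select_interactors`,
`epitrack.trafficking_assay.analyze_panel`, ...), and `epitrack run --config
run.yaml` executes configured stages end to end into a run directory with a
seed- and config-hash-stamped `summary.json`.

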