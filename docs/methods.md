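# Methods

`epitrack` reimplements, as reusable and tested code, the quantitative
workflow of a bait-interactome and membrane-trafficking study: SILAC AP-MS
interactor selection, interactome community detection, term
over-representation, image colocalization, antibody-quench
endocytosis/recycling quantification, and comparative-Ct expression analysis.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## SILAC interactor screen

**Model.** Each protein carries heavy/light (H/L) intensity pairs over
biological replicates; the bait pull-down is labeled heavy, the control
pull-down light, so the H/L ratio is the enrichment readout. Mass-spectrometry
noise is multiplicative, so all tests operate on log intensities / log2
ratios.

**Statistics.** Two test modes coexist in the literature for this design and
both are implemented; the contradiction is surfaced, not resolved:

* `two_sided_unpaired_intensity` (default): pooled-variance unpaired t-test on
  log heavy vs log light intensities (4 df for a 3-vs-3 design).
* `one_tailed_log_ratio`: one-sample t of the replicate log2 ratios against 0,
  upper tail.

Degenerate cases are explicit: zero variance with equal group means gives
p = 1; zero variance with unequal means gives the smallest representable
positive p plus a `degenerate` flag (a noise-free fold change is evidence, but
its magnitude is not estimable).

The permutation FDR rebuilds the null by reassigning the 2k per-protein
intensities into pseudo-heavy/pseudo-light halves — exhaustively when
C(2k, k) ≤ 64 (all 20 assignments for three replicates), randomly otherwise —
pooling null statistics over proteins, and computing
q = (mean null count ≥ observed) / (observed count ≥ observed), capped at 1
and monotonized in the observed statistic.

**Selection filter** (defaults): mean H/L ratio > 3, p ≤ 0.05, ≥ 2 unique
peptides, quantified in all replicates. The mean ratio is the arithmetic mean
of the replicate ratios (a geometric mode is behind a flag) because published
tables of this kind print arithmetic means. "In all independent experiments"
is read as *quantified in all replicates with the criteria applied to
replicate-aggregate statistics* — published tables print one mean ratio and
one p per protein — while a strict per-replicate fold mode is available
behind `per_replicate_fold`. Ratios with zero/missing light intensity are
excluded from the mean with an audit flag rather than becoming infinite.

The packaged fixture `data/table1_epcam_interactors.tsv` transcribes the
published 78-row interactor table (bait included) with its printed mean
ratios, unique-peptide counts and p values; those p values are taken as given
and never recomputed, since the underlying replicate data are not public. One
unique-peptide count was illegible in the source transcription and carries a
placeholder (marked in the file header); it cannot change any selection
decision.

## Interactome communities

The interactor graph is the subgraph of a STRING-style edge list induced on
the selected interactors, isolated interactors kept as singletons. Community
detection is divisive edge-betweenness clustering: remove a
maximal-betweenness edge, recompute, record the component structure, and
return the partition along the removal sequence that maximizes Newman–Girvan
modularity

Q = Σ_c [e_c/m − (d_c/2m)²]

computed on the *original* graph. Betweenness is exact Brandes shortest-path
edge betweenness (networkx), unweighted by default even when confidence
scores are present (matching the default behavior of the classical
algorithm); a weighted mode exists behind a flag. Ties on maximal betweenness
are broken by removing the lexicographically smallest edge, which makes the
sweep fully deterministic without a seed. An edgeless graph yields singleton
communities with Q = 0; disconnected inputs are handled per component with
globally unique community ids. Because the divisive sweep only visits
partitions reachable by edge removals, the returned Q can fall below the
global modularity optimum on adversarial graphs; tests assert dominance over
every partition the sweep visits and exact agreement with brute force on the
canonical cases (bridge graphs, disjoint cliques).

## Term over-representation

One-sided Fisher's exact test per term: p = P(X ≥ k) for a hypergeometric X
with query size n, term size K and background size N. The background is
always an explicit id list — the whole set of quantified proteins — never an
implicit genome-wide default; a query id missing from the background is an
error, not a silent drop. Benjamini–Hochberg adjustment is applied within
each annotation namespace (BP, CC, MF and KEGG are separate families,
mirroring per-panel reporting). Terms with zero query members are excluded
from testing by default (they are untestable and only inflate the family
size); an include-all flag exists. Chord-diagram export produces the
long-format (protein, ratio, term) table for the top-ranked terms and reports
how many query proteins are covered.

## Colocalization

Threshold-Manders coefficients with manual thresholds t_A, t_B:

M1 = Σ_{A>t_A} A·[B>t_B] / Σ_{A>t_A} A,  M2 = Σ_{B>t_B} B·[A>t_A] / Σ_{B>t_B} B.

The denominator is restricted to the channel's own supra-threshold pixels
(the convention of the standard ImageJ colocalization plugin); a
total-intensity denominator is behind a flag. Thresholds are manual inputs by
design — no automatic estimation. Channel A is the bait (e.g. EpCAM-YFP) and
channel B the marker (mCherry-Rab5/7/11, lysotracker), so M2 is "fraction of
marker overlapping the bait". A zero denominator (no supra-threshold signal)
raises naming the channel. Condition comparisons aggregate per-image-area
coefficients and report a Welch t-test descriptively; with fewer than two
areas per condition only the summary is produced.

## Endocytosis and membrane recycling

**Assay structure.** Five flow-cytometry groups: unstained, 100 % labeled,
quench background (labeled then quenched), endocytosis (internalize 30 min,
quench), recycling (internalize, quench, chase 30 min, quench again). Live
cells are gated first; when no gate is supplied a permissive 1st–99th
percentile FSC/SSC rectangle is used (real gates are instrument-specific and
rarely reported). MFI is the arithmetic mean (a geometric option exists for
heavily log-normal data).

**Normalization chain.** net(g) = [MFI(g) − MFI(unstained)] −
[MFI(quench_bg) − MFI(unstained)] = MFI(g) − MFI(quench_bg). Then

endocytosis_rate = net(endocytosis) / net(labeled_100),
recycling_rate (positive convention) = (net(endo) − net(rec)) / net(endo).

The quench-background subtraction cancels the residual unquenched surface
term (1−q)·S *exactly* in expectation, so the endocytosis estimator is
unbiased for any quench efficiency q — a property the tests verify on a grid
q ∈ {0.8, 0.9, 1.0}.

**Sign convention.** The formula often printed for recycling,
(net(rec) − net(endo)) / net(endo), is negative for true recycling under any
model in which recycled label returns to the surface and is quenched: the
recycling arm can only lose protected signal relative to the endocytosis arm.
The package therefore defaults to the `positive_recycling` convention (its
negative), reports the as-printed value alongside, and logs the discrepancy
in every report.

**Rate uncertainty.** Delta-method standard errors propagate the per-group
event variances through both rate formulas (the three group means entering
each rate are independent).

**Plateau rule.** For a timecourse of endocytosis rates, the plateau is the
earliest timepoint after which every successive increase is ≤ ε·(max − min)
of the rate range (ε = 0.1 by default). The final timepoint never qualifies
vacuously; fewer than three timepoints yield rates only.

## Comparative Ct (ΔΔCt)

Technical replicates averaged per (sample, gene); ΔCt = Ct(gene) −
Ct(housekeeping) within a sample; ΔΔCt = ΔCt − mean reference-group ΔCt;
RQ = 2^(−ΔΔCt). A single housekeeping gene per run (GUSB for the murine
panels, GAPDH for human ones); multi-gene geometric-mean normalization is out
of scope, as is efficiency (Pfaffl) correction. Per-sample RQs are emitted so
biological scatter stays visible; the group RQ is 2^(−mean ΔΔCt), which makes
the reference group's geometric-mean RQ exactly 1 by construction.

## Synthetic data: what it emulates and what it does not

All generators draw from a single `numpy.random.Generator` per call —
identical parameters and seed give byte-identical serialized outputs.

* **SILAC screen.** Heavy and light channels are *independent* log-normal
  measurements around a shared per-protein abundance, with per-channel log2
  noise `ratio_sd/√2`, so replicate log2 ratios are exactly
  Normal(planted log2 fold, ratio_sd) and the pooled unpaired t-test is
  exactly calibrated under the null. Unique-peptide counts are
  1 + Geometric(p): heavy-tailed small counts as in real interactor tables
  (observed range 2–61). Not emulated: shared per-replicate loading effects
  (which would make the unpaired test conservative), missingness, ratio
  compression, protein-inference artifacts. Defaults (500 background
  proteins, 40 planted interactors at 8-fold, ratio_sd 0.3, 3 replicates)
  put the planted effect far above the selection cutoff, the regime of a
  strong bait pull-down.
* **Flow panels.** Per-cell autofluorescence A and surface label S are
  log-normal (flow data are approximately log-normal; strictly positive MFIs
  and realistic CVs). Quench removes a deterministic fraction q of
  surface-exposed fluorescence per application; the second quench in the
  recycling arm re-applies q to everything surface-exposed at that time.
  Ongoing internalization during the chase moves a fraction f of the surface
  pool inside, and internalized *quenched* label regains fluorescence
  (quench-antibody dissociation in acidified endosomes). This dequenching
  term is what lets the recycling arm end up brighter than the endocytosis
  arm, so apparently negative recycling — the signature of residual ongoing
  internalization — is reproducible; without it, a quench-chase model can
  only lose signal in the recycling arm and the positive-convention rate
  can never go negative. At f = 0 the composition reduces exactly to the
  plain quench model. Default planted fractions (e = 0.0825, r = 0.5993)
  are the teratoma-cell operating point of the assay. Not emulated:
  spillover/compensation, doublets, dead-cell scatter, cell-to-cell kinetic
  heterogeneity.
* **Colocalization images.** Gaussian spots on a jittered grid whose pitch
  guarantees spots from different sites never touch; a planted fraction of
  channel-B spots sits exactly on channel-A sites. With zero background and
  noise, the fraction of B's integrated intensity on A-positive pixels equals
  the planted fraction to one-spot granularity, so M2 recovery is exact. Not
  emulated: real point-spread functions, chromatic shift, shot noise
  structure.
* **Ct tables.** Ct = baseline − log2(expression) + noise, with a per-sample
  loading offset that the housekeeping normalization must cancel (and tests
  verify it does). The housekeeping gene is flat across groups by
  construction — a validated invariant, since a drifting housekeeping gene
  invalidates ΔΔCt in practice too.

Passing tests on these generators show the *estimators* are correct under
their stated models; they do not show robustness to the unmodeled artifacts
listed above.

## Problem sizes and numerics

Simulation-based tests use 10,000–100,000 events per flow group (enough for
three-standard-error recovery bands of ±0.2–1 percentage point), 3,000
background proteins for null calibration, and timecourses of six 5-minute
samples at 60,000 events per group, where the plateau detector's decision
margins are ≥ 2.5 Monte-Carlo standard errors. Oracle-equivalence tolerances
are 1e-12 (Fisher, BH, Manders) and 1e-9 (betweenness); floating-point ties
in the Girvan–Newman sweep are regarded as equal within 1e-12 before the
lexicographic rule applies.

## Known limitations

* Published p values in the packaged interactor table cannot be recomputed
  (no replicate-level data); they are inputs, not outputs.
* The published experimental headline numbers of the underlying study (MFI-R
  shifts, condition-specific endocytosis/recycling percentages, bafilomycin
  fold changes) derive from raw cytometry and imaging data that are not
  deposited; the package reproduces the *estimators* and verifies them on
  planted ground truth instead.
* The divisive community sweep is O(V·E²) per component; it is meant for
  interactome-scale graphs (tens to hundreds of nodes), not genome-scale
  networks.
* FCS ingestion is not implemented; event tables are CSV with documented
  headers.
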