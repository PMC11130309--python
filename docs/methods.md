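# Methods

This note describes the models and procedures implemented in `tamscreen`,
the choices made where the design was genuinely open, and what the
synthetic data can and cannot establish about real experiments.

## The analysis chain

The package implements a complete screen for tumor–macrophage
communication programs that behave discordantly between a PARP-inhibitor
sensitive and a resistant tumor model:

1. **Synthetic experiment generation** (`tamscreen.simulate`) — replicated
   single-cell experiments with known ground truth.
2. **Quality control** (`tamscreen.qc`) — cell filtering, simulated-doublet
   flagging, hashtag demultiplexing, normalization, HVG selection, in the
   fixed order filter → doublets → demux → normalize → HVG.
3. **Annotation** (`tamscreen.annotate`, driven by
   `tamscreen.pipeline.annotate_experiment`) — ordered marker rules for
   lineages, DEG-pair rules for TAM/monocyte subtypes, and the
   C5ar1-high/low split of TAM_C3.
4. **Interaction calling** (`tamscreen.interactions`) — per-sample
   ligand–receptor scoring with an expression gate and a permutation null.
5. **Differential counting** (`tamscreen.diffcount`) — the
   replicate-pairwise interaction count estimate
   `N = Σ_units (n_up − n_dn)` over all `a×b` cross-condition sample
   pairs, receptor-level aggregation, and the discordance screen.
6. **Signature scoring** (`tamscreen.scoring`) — rank-based (UCell-style)
   per-cell scores, within-sample Z-ranks across subclusters,
   binned-control pathway scores, pseudobulk Pearson correlation.
7. **Cohort outcomes** (`tamscreen.cohort`) — C5aR1hi/CD86hi myeloid
   classing, the pseudocounted count ratio, upper-quartile stratification,
   Mann–Whitney ROC, Kaplan–Meier/log-rank, and univariate Cox regression.

## Synthetic count model

Counts are negative binomial. Cell *c* of type *t* in arm *a* has gene-*g*
mean

```
mu(c,g) = L_c · s_g · m(t,g) · q(a,t,g) / Σ_g' s_g' · m(t,g') · q(a,t,g')
```

where `s_g` is a baseline relative-expression share (fixed for the ~70
named marker/ligand/receptor/mitochondrial genes, log-normal for filler
genes), `m(t,g)` the marker-table multiplier, `q(a,t,g)` the planted
program multiplier, and `L_c` a log-normal library size (default mean
12 000, σ = 0.35). Dispersion is shared (`θ = 2`, variance `μ + μ²/θ`).
Renormalizing the shares within each cell keeps library sizes independent
of the marker structure.

Key default parameters:

| parameter | default | why |
|---|---|---|
| cells per sample | 1000 | desk-scale replicate with ≥50 cells in each minor population |
| design | sensitive/resistant × vehicle/treated; 2 vehicle + 4 treated replicates per model | the study design this emulates |
| genes | 2000 (≈70 named + 8 mito + filler) | smallest universe in which the 1000-detected-genes QC rule behaves like it does on real 10x data |
| per-type program genes | 20 at ×6 | real cell types differ by broad transcriptional programs, not only by a handful of markers; without these, unsupervised clustering cannot separate subtypes that share lineage markers, which would be an artifact of the simulation rather than a property of the method |
| doublet rate | 6% | matches the QC module's expected rate |
| low-quality cells | 3%, library ×0.08, mito ×6 | gives the QC filter something real to remove |
| C5ar1 in TAM_C3 | bimodal: 50% of cells ×400 over a near-silent baseline | the C5ar1-high/low dichotomy inside TAM_C3; detection (count > 0) then recovers the planted fraction |

The planted program (malignant Rps19 → TAM_C3 C5ar1) multiplies the
ligand mean in sender cells and the receptor mean in receiver cells by an
arm-dependent strength: 1.0 in resistant-treated and sensitive-vehicle,
0.005 in the other two arms. The receptor's detection fraction in TAM_C3
therefore crosses the 10%-of-cells expression gate exactly when the
program is on, which is what makes the interaction call flip with
treatment in opposite directions in the two models. A `null=True` variant
sets every arm to 1.0: the interaction is then present everywhere and the
differential screen should return nothing.

What the generator does **not** emulate: ambient RNA, batch effects,
spliced/unspliced layers, realistic gene–gene correlation beyond the
type-level programs, and continuous differentiation trajectories. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every artifact of real 10x data.

## QC

* Cell filter: keep iff detected genes ≥ 1000 **and** mitochondrial UMI
  fraction ≤ 20%. Both published thresholds are exclusions phrased
  strictly ("fewer than", "more than"), so boundary cells are kept. The
  published phrasing conflates genes and UMIs ("fewer than 1000 genes
  detected (UMI > 1000)"); the detected-genes reading is the default and a
  separate optional UMI floor is exposed (`QCThresholds.min_umi`).
* Doublets: simulated doublets (sums of random observed-cell pairs; pool
  size = 5 × expected rate × n, minimum 300) are embedded with the
  observed cells in a PCA of the 250 most variable log-normalized genes;
  a cell's score is the fraction of its 10 nearest neighbors that are
  simulated, and cells above the 95th percentile of scores are flagged.
  This is a deliberate simplification of Scrublet that keeps its two
  published parameters; note that a 95th-percentile cut can flag at most
  5% of cells, which caps recall when the true doublet rate is higher.
* Demultiplexing: Leiden communities (resolution 1.2) on a kNN graph of
  log-normalized tag counts; a community is assigned to a tag only when
  that tag is the per-cell argmax for ≥ 90% of members and no other tag
  exceeds the complement (`dominance_fraction`, configurable — the source
  procedure requires only "exclusively unique" capture).
* HVG: dispersion (variance/mean of log-normalized expression) z-scored
  within 20 equal-count mean-expression bins; ties broken by gene symbol
  so the mask is reproducible; default 4000 genes, capped at the number of
  non-constant genes.

## Annotation

"Expressed" for a marker rule is decided at cluster level: the cluster's
mean normalized expression z-scored across clusters must exceed 0.5 and be
positive (a per-cell detected>0 mode exists). Rules are evaluated in their
listed order and the first match wins, which resolves profiles satisfying
several rules (e.g. proliferative Tregs). Myeloid subtype assignment
branches on relative Cd14 vs Cd68 (monocyte vs macrophage), then takes the
subtype whose characteristic DEG pair has the highest mean z-score within
the myeloid compartment.

The pipeline obtains cluster labels from a thin PCA+KMeans helper (25
coarse clusters; the T and myeloid compartments are then sub-clustered and
re-annotated, mirroring the common practice of re-clustering compartments
of interest). Clustering internals are deliberately plumbing: any label
vector can be supplied instead. Malignant cells are identified by a
provided mask (ground truth in synthetic data; in real data this is where
a CNV-based caller would plug in), applied at cluster level by majority.

## Interaction calling and the permutation null

For each ordered (sender, receiver) type pair of the communication axes of
interest and each database pair: the ligand must be detected in strictly
more than 10% of sender cells and the receptor in more than 10% of
receiver cells, each type must have ≥ 10 cells, and the strength is the
product of 10%-per-side trimmed means ("the central 80% of cells"). The
trimmed mean drops `ceil(trim·n)` cells per side when `trim·n` is
fractional, so 6 cells at trim 0.10 keep the central 4. The null shuffles
type labels over the union of the two types; `p = (1 + #{null ≥ obs}) /
(1 + n_perm)` never reaches zero and is super-uniform under
exchangeability. Permutation draws are shared across all database pairs of
one type combination. Zero strength short-circuits to p = 1.

The end-to-end pipeline scores the tumor↔myeloid axes (malignant →
each TAM/monocyte subtype and the reverse) rather than all ~200 ordered
type pairs: the screen's question is about tumor–TAM communication, and
restricting the universe avoids flooding the differential statistic with
biologically irrelevant sender types that merely share a broadly expressed
ligand.

## The interaction count estimate and the screen

Every condition-A sample is compared with every condition-B sample
(`a×b` ordered pairs; no within-condition pairs). Per unit and pair the
default call is presence-based: up iff significant in the A sample and not
in B, down for the converse; units absent from both are unchanged. A
strength-fold alternative (up iff `strength_A ≥ τ·strength_B` among rows
significant in either; τ = 1.5) is available, since the source procedure
does not pin down what "increased" means per pair; the choice is recorded
in the result's design. Counts are exact integers; `N = n_up − n_dn` per
unit, summed over a receptor's ligands for receptor-level counts.

The discordance screen returns units with `N_resistant ≥ +m` and
`N_sensitive ≤ −m`. The pipeline's default threshold is
`m = ceil(0.75·a·b)` (6 for the default 4×2 design). Rationale: a single
vehicle replicate flipping significance by chance moves `N` by the number
of treated samples (4 here), so `m = a·b/2` admits single-replicate noise;
three-quarters of the maximum requires consistent behavior in both
conditions while still tolerating one discordant comparison pair of the
planted program.

## Signature and pathway scores

The rank-based score ranks all genes within a cell by expression
(descending, mid-ranks for ties), caps ranks at `r_max = 1500`, and maps
the Mann–Whitney statistic of the signature genes to
`max(0, 1 − U/(n·r_max))`. It is exactly invariant under monotone
transforms of the cell's expression vector. Signatures default to the top
3 DEGs per subcluster by Wilcoxon rank-sum against the rest (ranked by the
signed statistic, ties by symbol). Z-ranks standardize subcluster *mean*
scores within each sample (mean 0, SD 1 across subclusters); a sample
with a single subcluster is undefined and flagged. Pathway scores are
binned-control scores (scanpy's score module; 25 expression bins, 50
control genes per signature gene, seeded). Pseudobulk significance is the
strict rule r > 0.3 and p < 0.05 with p from the exact t transform; an
unsigned |r| variant is available because the published rule is ambiguous
for negative correlations.

## Cohort outcomes

Myeloid cells are classed with precedence C5aR1hi (C5AR1 detected) →
CD86hi (CD86 at or above the top-25% cut among expressing cells, with
C5AR1, CD163, MRC1 all undetected) → other. The ratio uses pseudocount 1
(zero CD86hi counts occur in small biopsies). The upper-quartile cut uses
linear-interpolation quantiles with ties assigned high. AUC is
`U/(n₁n₂)` with ties worth ½ and a tie-corrected normal p. The Cox fit is
damped Newton–Raphson on the Breslow partial likelihood with Wald CIs from
the observed information; monotone likelihoods are detected by a runaway
coefficient and flagged instead of looping. Breslow was chosen as the
simplest well-defined tie convention; the synthetic cohorts have
continuous times, where Breslow and Efron coincide. Kaplan–Meier curves
and the log-rank statistic are delegated to lifelines; the test suite
checks the log-rank statistic against an explicit hand computation.

The cohort generator draws per-patient myeloid class counts from a
Dirichlet-multinomial around (15% C5aR1hi, 25% CD86hi, 60% other),
survival from an exponential model with hazard
`h₀·exp(β·z)` on the cohort-standardized ratio (defaults `h₀ = 1/365`
per day, `β = 0.8`), independent exponential censoring (≈25%), and
non-response from a logistic model in the same covariate (coefficient
1.5, which at n ≈ 18–20 yields AUCs in the low 0.8s, the regime the ratio
statistic is meant for).

## Numerical choices and degenerate inputs

* All randomness flows from integer seeds through `numpy` `SeedSequence`;
  identical seed + configuration reproduces bit-identical data.
* Sparse matrices are CSR; normalized expression is float32 (memory
  bandwidth dominates the pipeline; the statistics are insensitive at this
  precision and the exactness guarantees concern integer counting and
  rank arithmetic, which are unaffected).
* Trimmed means fall back to the plain mean when trimming would empty the
  vector (n ≤ 2·ceil(trim·n)).
* Zero-denominator label ratios are +inf with a degenerate flag;
  zero-variance correlation variables are NaN and never significant;
  all-zero cells abort normalization with the offending row named.
* Problem sizes in the test suite and acceptance script (10 recovery
  seeds + 50 null seeds at 1000 cells/sample, 200 permutation-null units,
  100 Cox recovery and 500 coverage replicates) are the package's chosen
  desk-scale study conditions.

## Known limitations

* The interaction strength is this package's own documented statistic; it
  is not numerically comparable to CellChat's mass-action model, and no
  pathway-level aggregation is provided.
* `N` carries no significance of its own (none is defined for it); the
  screen is a ranking device.
* The doublet flag is a simplified surrogate; it is not Scrublet.
* Expression-space clustering quality is outside the contract: annotation
  is a pure function of (clusters, rules), and poor clusters degrade
  labels accordingly.
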