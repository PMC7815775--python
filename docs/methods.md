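# Methods

## Study design being modelled

Peripheral-blood samples from a radiation-exposed cohort are stratified by
annual absorbed dose into a reference group (I, < 1.5 mGy/y) and three
exposed groups (II: 1.5–5.0, III: 5.0–14.0, IV: > 14.0 mGy/y).  Proteins are
quantified with 4-plex isobaric tags: one pooled sample per group, the
reference pool on reporter label 114, and each exposed pool measured as a
reporter-ratio against it in two technical replicates.  The pipeline's
statistics operate on those ratios; peptide identification and protein
inference are upstream of its scope.

## Differential calling

For each protein × group, the two replicate ratios r₁, r₂ are augmented
with their arithmetic mean as an imputed third value (the mean of the *raw*
ratios, not of their logs — "mean fold change" semantics).  The triple is
log2-transformed and tested against 0 with a two-sided one-sample Student
*t* (df = 2); testing on the log scale makes the null "ratio = 1" and
symmetrises up/down regulation.  p-values are BH-adjusted within each
group; calls are *up* if FC ≥ 1.2 and adjusted P ≤ 0.1, *down* if FC ≤ 0.83
and adjusted P ≤ 0.1.

Numerical choices:

- A zero-variance pair (r₁ = r₂) has an undefined t statistic.  Such
  proteins are flagged `testable = False` with NaN p — never p = 0, which
  would fabricate top hits.
- %CV is computed over the two *real* replicates only; including the
  imputed mean would deflate it by construction.
- Proteins missing a replicate in a group are excluded from that group's
  testing and counted in the QC table.
- The KS normality check (log2 fold changes vs a fitted normal) is reported
  per group as QC and does not gate calls.
- BH ties are broken by stable sort on input order, so adjustment is
  deterministic and order-preserving.

Note that n = 3 obtained from 2 real measurements is pseudo-replication:
the imputed value shrinks the within-triple variance, making raw p-values
anti-conservative.  The fold-change gate dominates in practice (the
test-suite global-null check measures the realised false-call rate), but
p-values from df = 2 on a part-imputed triple should be read as a ranking
device, not calibrated error rates.

## Over-representation

One-sided Fisher's exact test: p = P(X ≥ k) with X hypergeometric over the
background universe.  The background is the set of *quantified* proteins,
not the genome — detection conditions both the selected and the term sets,
and using the genome would inflate significance.  Significance is at
unadjusted p ≤ 0.05 (the convention of the annotation tools this step
mirrors); a BH column is emitted for transparency.  Terms are intersected
with the background first; terms with no background overlap are skipped and
logged.  Output is sorted (p, then term id) so it is invariant to input
term order.

## PPI network analysis

Interactome files (edge-list TSV or minimal PSI-MITAB) are merged into one
simple undirected graph: self-loops dropped, duplicate unordered pairs
merged with source labels unioned.  Each group's network is the interactome
induced on the **union** of differential proteins across groups, annotated
with that group's log2FC.  The union (rather than per-group) list is what
makes "un-regulated" nodes possible in a group's network; isolated nodes
are dropped, which is why network protein counts are below differential
counts.  Modulation classes use strict cutoffs log2FC > 0.263 (up) and
< −0.263 (down); 0.263 is log2(1.2) to three decimals, tying node colouring
to the calling threshold.

GCC significance: the observed giant-connected-component size is compared
to a null in which node sets of the same size are resampled uniformly
without replacement from the interactome, and the induced GCC size is
recorded (B ≥ 1000; the permutation loop uses a plain adjacency-set BFS so
10⁵-scale permutations stay cheap).  z = (observed − null mean)/null sd;
the empirical p uses the add-one convention (#null ≥ observed + 1)/(B + 1),
which cannot be zero.  Uniform resampling is the default null because the
question is "is this GCC large for a selection of this size"; a
degree-stratified variant (resampling within degree deciles of the observed
selection) is available when degree bias is a concern.  Ties in the GCC
(two equal components) resolve to the component containing the
lexicographically smallest node id.

Node metrics: DC is raw degree; BC unnormalised shortest-path betweenness;
CC is (reachable − 1)/Σdistances within the node's component; clustering is
the local triangle density.  The hub score is log2FC × DC (raw degree), and
hubs are ranked by |score| — sign retained in output — so a strongly
down-regulated high-degree protein can top the list; ties break by higher
degree, then id.  Node size (DC + 1)(|log2FC| + 1) is attached for
visualisation.  Exports are GEXF and GraphML with all node/edge attributes;
the GEXF modification-date stamp is pinned so identical networks export
byte-identically.

## qPCR (2^−ΔΔCt)

ΔCt = Ct_target − mean(Ct of the two reference genes); the arithmetic mean
of Ct equals the geometric mean of linear quantities, the standard choice
for dual-reference normalisation.  ΔΔCt subtracts the *mean* ΔCt of the
calibrator group (a population calibrator rather than a single sample), so
the calibrator group's mean ΔΔCt is exactly 0 and its geometric-mean fold
change exactly 1.  Amplification efficiency is fixed at 2 (the method's
defining assumption); no efficiency correction.  Groups are compared to the
calibrator with a two-sample Student *t* on per-sample folds, reported as
mean ± SEM with n taken from the data.  Conventions: identical group means
give p = 1; unequal means with zero variance in both groups are flagged
degenerate (NaN) rather than p = 0.  Reference-gene stability (sd of Ct
across all samples, default threshold 1 cycle) is validated first and
failure warns without halting.

## Dosimetry

annual dose = (indoor_rate × f + outdoor_rate × (1 − f)) × 0.0767, with f
the indoor-occupancy fraction and rates in μR/h.  The module applies the
constant 0.0767 as printed in the survey literature it follows (the
underlying product 0.8763 × 24 × 365 × 10⁻⁵ = 0.076764 was truncated, not
rounded, to four decimals there; using the printed value keeps doses
consistent with that convention).  The 1.5 mGy/y boundary is quoted
inclusively on both sides in the field's own usage; here exactly 1.5 maps
to Group II (HLNRA) by default, configurable.  Upper cuts are half-open at
5.0 and 14.0 since doses are continuous.  Internal (ingested/inhaled) dose
is out of scope.

## Synthetic-data generator

The generator defines the conditions under which the pipeline is tested:

- **Quant**: 800 proteins by default, 10% planted regulated with |log2FC|
  uniform on [0.5, 1.5] (floor at log2 1.2 so every planted effect is
  callable in principle), replicate noise Normal(0, 0.1) on the log2 scale —
  multiplicative noise matching reporter-ratio error; 0.1 corresponds to
  ~7% CV, typical of well-behaved technical replicates.  The planted count
  is exactly round(n × fraction); signs split 50:50 by default with the
  up-fraction exposed (exposed-cohort data are up-dominated; the analysis
  drivers use 0.9).  A `group_presence` probability (default 0.9 in the
  pipeline config) makes most planted proteins shared across dose groups,
  giving a non-degenerate Venn partition.
- **Annotation**: 50 terms of 10–40 members; 5 enriched terms sample
  members with planted:null odds 8.
- **Interactome**: Barabási–Albert preferential attachment (m = 2) on 600
  of the proteins — scale-free like curated interactomes — plus a planted
  module of 20 planted proteins densified to edge density 0.8.
- **qPCR**: Ct noise sd 0.2 cycles, 5 samples per group, planted log2FC 1
  on alternating target genes, two stable reference genes.
- **Dosimetry**: subject rates uniform over 5–400 μR/h (spanning sub-mGy to
  tens of mGy/y annual doses); each reported rate is the mean of three
  readings, with reading noise 0 by default so reported rates are exact.

What the generator does **not** emulate: peptide-level identification and
roll-up, inter-protein abundance correlation, batch/run effects, missing
values beyond whole-replicate dropout, biological covariates (age,
smoking), annotation-term overlap structure, and literature-quality
interactome noise (false edges, study bias).  Passing tests therefore
demonstrate correctness of the statistics and the recovery of planted
signal under idealised noise — not performance on real LC–MS/MS data.

## Problem sizes and determinism

Default pipeline: 800 proteins, 600-node interactome, B = 1000 permutations
— a full run takes a couple of seconds and the whole test suite about half
a minute, so the planted-recovery and calibration checks (hundreds of
simulated datasets) stay routine.  The per-operation default for GCC
permutations is 10 000.  All randomness flows from a single run seed
through named substreams (numpy `SeedSequence`), and every output is plain
text with pinned metadata, so a rerun under the same configuration is
checksum-identical.

## Known limitations

- The differential test's p-values are anti-conservative by design of the
  imputation scheme (see above); FDR control is empirical, not exact.
- The GCC null resamples nodes uniformly; hub-biased selections can reach
  significance through degree alone (use the degree-stratified null to
  probe this).
- Identifier namespaces are taken as-is; no UniProt/symbol mapping.
- Enrichment ignores term-term dependence (no GO-graph propagation).
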