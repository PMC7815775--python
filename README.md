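# radprot

A tested re-implementation of a quantitative-proteomics analysis pipeline for
cohorts chronically exposed to elevated natural background radiation
(high-level natural radiation areas, HLNRA).  The pipeline covers five
stages, each usable on its own:

1. **Differential calling** from 4-plex isobaric-tag (iTRAQ) reporter
   ratios: three dose-group pools (labels 115/116/117) quantified against a
   reference pool (label 114) in two technical replicates.  The mean ratio
   serves as an imputed third replicate; log2 ratios are tested with a
   one-sample Student *t* (df = 2), BH-adjusted, and called *up* at fold
   change ≥ 1.2 / *down* at ≤ 0.83 with adjusted *P* ≤ 0.1.  %CV over the
   technical replicates and a Kolmogorov–Smirnov normality check are
   reported as QC.
2. **Over-representation analysis**: one-sided Fisher's exact test
   (hypergeometric upper tail) of the differential set in user-supplied GMT
   term sets, against the quantified-protein background, significant at
   *P* ≤ 0.05.
3. **Protein–protein interaction networks**: the merged interactome
   (edge-list TSV or minimal PSI-MITAB) induced on the union differential
   list, per-group fold-change annotation (up/down at |log2FC| > 0.263 =
   log2 1.2), giant-connected-component (GCC) size significance via a
   permutation null (uniform node resampling, empirical z and add-one
   p-value), hub ranking by |log2FC × Degree|, node size
   (DC + 1)(|log2FC| + 1), and GEXF/GraphML export.
4. **qPCR validation** by the Livak–Schmittgen 2^−ΔΔCt method with two
   reference genes, reference-stability validation, mean ± SEM and
   Student's *t* per group.
5. **Dosimetry**: survey-meter exposure rates (μR/h, indoor/outdoor) are
   occupancy-weighted and converted to annual absorbed dose with the
   0.0767 μR/h → mGy/y factor, then stratified into dose groups
   I (< 1.5 mGy/y), II (1.5–5.0], III (5.0–14.0], IV (> 14.0).

A synthetic-data module generates every input with planted ground truth
(regulated proteins, enriched terms, a dense interactome module, qPCR fold
changes), so the whole pipeline is testable end to end without any external
database.

## Worked example

Run the numbered drivers in `analysis/` (or equivalently
`radprot run-all --seed 11 --set up_fraction=0.9 --outdir results/run`):

```
$ python analysis/01_simulate.py
simulated inputs for 800 proteins (10% planted, 90% of them up) -> results/run

$ python analysis/02_differential.py
group II: 67 up, 8 down (75 differential of 800)
group III: 65 up, 7 down (72 differential of 800)
group IV: 67 up, 7 down (74 differential of 800)
Venn partition: {'II': 1, 'II&III': 5, 'II&III&IV': 61, 'II&IV': 8, 'III': 1, 'III&IV': 5, 'IV': 0}

$ python analysis/04_network.py
group II: 34 nodes / 161 edges; GCC 23 (null 7.0+/-4.4, z=3.66, p=0.0150); top hub P0335
```

Reading: of 800 quantified proteins, ~75 per dose group pass the
fold-change + adjusted-P gates (the 80 planted regulated proteins minus a
few borderline effects; most are shared across groups, as the Venn
partition shows).  The 34 differential proteins with any interaction form a
network whose 23-node GCC is far larger than the 7.0 ± 4.4 expected for a
random 62-protein selection (z = 3.66, empirical p = 0.015) — the planted
dense module is detected.  `05_qpcr.py` recovers the planted two-fold
mRNA changes (e.g. `G01 group II: fold 1.92 +/- 0.16, p=0.0011`), and
`06_dosimetry.py` stratifies the simulated subjects by annual dose.

Each stage writes its tables (TSV/JSON, plus GEXF/GraphML networks) under
the run directory; `summary.json` consolidates counts, enrichment, GCC
statistics, hubs and planted-truth recovery.

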