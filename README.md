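# enzatlas

How does a cell distribute its finite protein budget across the metabolic
network? Because the rate of an enzymatic reaction is proportional to enzyme
abundance, absolute enzyme concentrations bound the flux each reaction can
carry — and, at metabolite branch points where several enzymes compete for
one substrate, the relative concentrations estimate how strongly the network
commits that substrate to one route.

`enzatlas` is an analysis pipeline for absolute proteome tables — protein ×
cell-line matrices of cell protein copy numbers (CPC), the standardized
per-cell copy estimates derived from label-free mass spectrometry — combined
with a pathway membership map, a stoichiometric reaction network, and
kinetic/thermodynamic tables. It is aimed at systems biologists studying
how enzyme concentration is organized across metabolism (e.g. in cancer
cell-line panels such as the NCI-60). It computes:

- **Proteome partitioning** — a detection filter (proteins seen in only one
  sample or one tissue type are removed), the metabolic share of total
  mean-CPC mass, per-pathway abundance percentages per cell line, and
  log-binned relative-frequency distributions of CPC values.
- **Glycolysis profiling** — enzyme abundance ordered along the canonical
  glucose → lactate chain, and branch-point enzymes compared against the
  core enzyme acting on the same substrate (e.g. PHGDH vs PGAM at
  3-phosphoglycerate).
- **Branch-point analysis** — enumeration of metabolites consumed by ≥ 2
  reactions, branch divergence scores over enzymes ranked by mean CPC
  descending,

      BD_top2 = (C1 − C2) / C1 ∈ [0, 1]
      BD_top3 = (C1 − C2 − C3) / C1 ∈ [−1, 1]

  classification into *one-sided* (BD_top2 > 0.8) and *equally distributed*
  (BD_top2 < 0.2 or BD_top3 < 0) branches, score histograms (bin width 0.1,
  lower-end inclusive), and per-pathway Fisher exact tests between the two
  classes.
- **Cofactor usage** — enzymes whose reactions carry NAD+/NADH or
  NADP+/NADPH on either side (redox), or α-ketoglutarate (nitrogen
  assimilation), ranked by mean CPC.
- **Kinetics integration** — per-enzyme K_M cleaning (wild-type only,
  1.5·IQR outlier removal on log10) and geometric-mean aggregation, joining
  with reaction ΔG° and mean CPC, pairwise Pearson/Spearman correlations on
  (log10 CPC, log10 K_M, ΔG°), min–max scaling to [0, 1], and a
  threshold-based four-group partition (extreme K_M / very low ΔG° / highly
  expressed / moderate).

A first-class synthetic-data generator (`enzatlas.simulate`) emulates the
inputs — log-normal CPC with sparse detection and tissue structure, planted
pathways and branch points with known divergence, contaminated kinetic
tables — and emits a ground-truth manifest recomputable from the files, so
every stage has sharp parameter-recovery tests without any download.

## Worked example

```
enzatlas run-all --outdir demo --seed 3
```

generates a default-condition synthetic study (400 proteins × 20 cell lines
across 4 tissues, a 40-reaction network with two planted branch points) and
runs every stage. From `demo/summary.json` of that run:

```
"profile": {
  "metabolic_fraction_pct": 18.185362598638157,
  "removed_mean_cpc": 3638.457240607692,
  "retained_mean_cpc": 93060.6737170542,
  "top_pathway_by_median_pct": "Glycolysis",
  "top_pathway_median_pct": 9.544647985199237, ...
},
"glycolysis": { "peak_step": 6, ... },
"branch": { "n_branches": 6, "one_sided": 4, "equally_distributed": 1, ... }
```

Reading: metabolic proteins carry ~18% of total mean-CPC mass; the proteins
removed by the detection filter average ~3.6 k copies against ~93 k for the
retained proteome (why they are excluded from global statistics); glycolysis
is the top pathway by median share (~9.5% of the proteome per cell line);
the sequential profile peaks at step 6 (GAPDH); and of the six branch points
found in the network (two planted, four arising from shared cofactor
metabolites), four are one-sided and one equally distributed, with both
planted branches landing in their planted classes as `demo/manifest.json`
confirms. Per-stage TSVs
(`pathway_fractions.tsv`, `branches.tsv`, `bd_hist_top2.tsv`,
`redox_ranking.tsv`, `kinetics_joined.tsv`, …) carry the full tables.

Real data drop in the same way: point `--indir` at a directory containing
`cpc_matrix.tsv` (or `.csv`/`.xlsx`), `tissues.tsv`, `pathway_map.tsv`,
`network_stoichiometry.tsv` + `reaction_meta.tsv` (or an SBML-subset file),
`km_table.tsv` and `thermo.tsv`, and skip the simulate stage.

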