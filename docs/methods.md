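# Methods

## The data model

The central object is a protein × cell-line matrix of cell protein copy
numbers (CPC) — dimensionless per-cell copy estimates derived upstream from
label-free mass-spectrometry quantification — with one tissue-of-origin
label per cell line. An empty entry means *not detected*, which the whole
package treats as distinct from a measured zero: detection is defined as
*present and strictly positive*. This matters because label-free proteomics
tables mix structural missingness (peptides never observed) with genuine
low abundance, and every detection-based rule below hinges on the
distinction.

Around the matrix sit three annotation layers: a many-to-many pathway →
protein membership map (KEGG-style; a protein in ≥ 1 pathway is
*metabolic*), a stoichiometric reaction network with signed coefficients
(negative = consumed), a reversibility flag and reaction → enzyme /
reaction → pathway maps (Recon-style), and kinetic tables: per-enzyme K_M
replicates (mM) with wild-type flags and per-reaction standard Gibbs
energies ΔG° (kJ/mol).

## Proteome partitioning

**Detection filter.** A protein is removed when its detections span fewer
than two cell lines or fewer than two tissues. The filter is idempotent and
reported, and the mean CPC of removed vs retained proteins (over detected
entries only) is emitted as the motivating contrast: rarely detected
proteins are also order-of-magnitude less abundant.

**Average CPC.** A protein's "average CPC across all cell lines" treats
absent entries as zero — the mean runs over the full panel — so that a
protein detected in 3 of 20 lines is not credited with its detected-only
mean. The alternative (mean over detecting lines only) is available via
`absent_as_zero=False`; both are legitimate readings of "average across all
cell lines" and the default is the conservative one for mass accounting.

**Fractions.** Metabolic % = 100 × (mean-CPC mass of metabolic proteins) /
(total mean-CPC mass); metabolic and non-metabolic shares sum to 100
exactly. Pathway percentages are per cell line, with the *total* proteome
CPC of that line as denominator (comparable with the metabolic %); a flag
switches to a metabolic-only denominator. Multi-membership proteins count
fully in every pathway they belong to, so pathway percentages do not sum to
100. Pathways with no detected members are reported and flagged, never
dropped.

**Binned distributions.** CPC values are binned into half-open intervals
[10^(k·w), 10^((k+1)·w)) anchored at 10^0, with w = 0.3 for proteome-wide
distributions and w = 0.2 for the glycolysis view; frequencies are relative
and sum to one. The anchor is a convention (the bin edges are only defined
up to translation); 10^0 keeps edges at round powers.

## Glycolysis profiling

The core pathway ships as an editable TSV: eleven steps from glucose to
lactate (HK2, GPI, PFKP, ALDOA, TPI1, GAPDH, PGK1, PGAM1, ENO1, PKM, LDHA,
with the aldolase products traversed via DHAP → GAP), each optionally
annotated with branch enzymes that divert the step's substrate (G6PD and
PGM1 at G6P, GFPT1 at F6P, GPD1 at DHAP, PHGDH at 3-phosphoglycerate, GPT
and PDHA1 at pyruvate). This is a best-effort reconstruction of the
canonical chain — isoenzyme choices are conventions, which is why the file
is data, not code. Steps with several isoenzymes are summarized by the sum
of their CPCs by default (max available); per-isoenzyme rows are always
emitted. Output order is a pure function of the pathway definition, never
of abundance. The branch-vs-core table reports the branch/core mean ratio
(scale-invariant) and the *exceedance count* — in how many cell lines the
branch enzyme reaches or exceeds the core enzyme on the same substrate.

## Branch-point analysis

A branch point is a metabolite consumed as a reactant by ≥ 2 distinct
reactions. Only the declared reactant side counts by default; a flag also
counts the product side of reversible reactions. No currency-metabolite
exclusion is applied by default (faithful to treating the network as
given), but an exclusion list is supported because ubiquitous cosubstrates
(ATP, H2O, cofactors) otherwise dominate branch counts — the synthetic
network deliberately exhibits this through its cofactor-coupled reactions.

Branches with identical consuming-reaction sets are repeats (one reaction
pair consuming two shared substrates) and collapse to one record; a branch
is retained only when every consuming reaction has a mapped, measured
enzyme. Routes are ranked by mean CPC descending — a reaction with several
isoenzymes takes their summed mean CPC (max available) — with ties broken
by enzyme id for determinism. Scores:

    BD_top2 = (C1 − C2) / C1,   BD_top3 = (C1 − C2 − C3) / C1

over the ranked concentrations. BD_top2 ∈ [0, 1], BD_top3 ∈ [−1, 1] and
BD_top3 ≤ BD_top2 always; both are invariant to rescaling all CPCs.
Classification uses strict thresholds: one-sided if BD_top2 > 0.8 (a flag
also admits BD_top3 > 0.8), equally distributed if BD_top2 < 0.2 or
BD_top3 < 0, otherwise unclassified; a score of exactly 0.8 or 0.2 is
unclassified. Histograms use bins of width 0.1, lower-end inclusive, with
the top edge folded into the last bin.

For enrichment, each classified branch contributes its top-2 ranked routes'
enzymes (top-3 where a three-route score exists) as unique (branch, enzyme)
pairs — an enzyme appearing at several branches counts once per branch,
never twice within one. Per pathway, a 2×2 table (in pathway vs not) ×
(one-sided vs equally distributed) gets a two-sided Fisher exact p-value;
raw p < 0.05 marks significance, with Benjamini–Hochberg adjustment behind
a flag. The count ratio (one-sided / equally distributed) is reported with
zero denominators flagged rather than silently dropped.

## Cofactor usage

Classification is purely structural: an enzyme is NAD-linked (NADP-linked)
if any reaction it catalyzes carries NAD+/NADH (NADP+/NADPH) among its
reactants *or* products — both sides, so reversible reactions are caught —
and an aminotransferase-style nitrogen handler if its reaction carries
α-ketoglutarate. Metabolite ids are matched through a packaged synonym
table after lowercasing and stripping compartment tags (`_c`, `[m]`, …);
compartment pools can be kept separate with a flag. A direction annotation
records which side the cofactor appeared on, but no physiological
producer/consumer sign is inferred — that requires flux direction, which
abundance alone does not give. Ranking by mean CPC is independent of the
classification.

## Kinetics integration

K_M records flagged non-wild-type are discarded first. Outliers are then
removed per enzyme on the log10 scale using the 1.5·IQR fence — K_M scatter
across experiments is multiplicative, so the fence is computed on logs. The
per-enzyme aggregate is the geometric mean of survivors (arithmetic behind
a flag), with the contributing count reported; enzymes left with no records
are reported, not silently dropped. ΔG° is per reaction; an enzyme takes
its primary (first-listed) reaction's value, with an expand-to-all-pairs
flag. Correlations are reported both as Pearson and Spearman on (log10 CPC,
log10 K_M, ΔG°), since the underlying claim — that the three variables are
mutually uncoupled — does not specify a coefficient.

For the grouping, each variable is min–max scaled to [0, 1] (log10 scale
for CPC and K_M, linear for ΔG°). The four-group partition replaces a
manual visual grouping with explicit, configurable thresholds applied in
fixed order so the result is reproducible and exhaustive: group 3 if
scaled K_M ≥ 0.9 (extreme K_M — appreciable forward flux requires substrate
buildup); else group 4 if scaled ΔG° ≤ 0.1 (strongly exergonic, effectively
irreversible); else group 2 if scaled CPC ≥ 0.9 (highly expressed without
extreme kinetics, the glycolysis-like regime); else group 1 (moderate in
all three). The precedence K_M → ΔG° → CPC resolves the rare overlaps
toward the kinetic extremes, which are the informative ones.

## The synthetic generator

The generator emulates an NCI-60-like absolute proteome study and is the
test bed for every stage. Default conditions, chosen once as a realistic
desk-scale study: 400 proteins × 20 cell lines over 4 tissues; log10 CPC
normal with mean 4.2 and SD 0.8 across proteins (arithmetic-mean CPC in the
tens of thousands of copies, the scale of deep cell-line proteomes) and
0.2 decades of per-cell-line scatter; 90% detection; 15% of proteins
metabolic, distributed over generic pathways plus one planted dominant
pathway (12 proteins, 6× abundance) and a canonical glycolysis block whose
step means are non-monotonic with the primary peak at GAPDH and a secondary
peak at enolase; 5% rare proteins (detected in one line or one tissue,
1.4 decades less abundant — the regime the detection filter targets); a
40-reaction network of linear chains plus two planted branch points
(targets BD_top2 = 0.9 and 0.1) and NAD/NADP/α-ketoglutarate-coupled
reactions; K_M tables with 4 replicates per enzyme, 0.15 decades of
scatter, 5% outlier and 10% mutant contamination, geometric-mean K_M
~0.3 mM; ΔG° ~ N(−10, 15) kJ/mol; no planted correlation between the
three kinetic variables (the null the analysis reports against).

Planted branch scores are realized *exactly*: per-enzyme target means are
solved analytically (C2 = C1·(1 − BD2); a requested BD2 = 1 is
epsilon-floored at C2 = 10⁻⁶·C1 and flagged in the manifest), per-line
log-normal noise is drawn, and each branch enzyme's row is rescaled so its
absent-as-zero mean equals the target — sharper than the 0.02 realization
tolerance the recovery tests assume. Planted correlation between log10 CPC
and log10 K_M uses the standard z-mixture construction
(z_km = r·z_cpc + √(1−r²)·ε), so r = 1 is exact and r = 0 leaves sampling
noise ~1/√n. The manifest records only quantities recomputable from the
emitted files (the realized metabolic fraction after the documented filter,
realized branch scores and expected classes, incidental branch points found
by brute-force scan — the cofactor metabolites — realized cofactor
rankings, true K_M per enzyme and the planted correlation), and identical
configurations produce byte-identical files.

What the generator does *not* emulate: peptide-level quantification and the
intensity-to-copy regression (CPC values are drawn, not derived),
abundance correlation structure across cell lines beyond a shared
per-protein mean, compartmentalized cofactor pools, and realistic network
topology beyond chains + planted branches + cofactor coupling. Passing
recovery tests therefore demonstrate correctness of the analysis logic
under the stated generative assumptions, not robustness to the full
messiness of real proteomes; real-data conclusions still require the real
tables.

## Numerical choices and degenerate inputs

Log-bin assignment guards against floating-point edge error by nudging
values that land exactly on an edge into the bin they lower-bound. BD
ranking ties break lexicographically. A zero top-ranked concentration makes
BD scores undefined (error, not NaN). Scaling a constant variable, an empty
matrix, binning an empty value set, or correlating fewer than three joined
enzymes raise explicit errors. The enrichment test with an empty class is
an error rather than a vacuous result. All outputs are written atomically
(temp file + rename), so interrupted runs never leave truncated TSVs.

## Problem sizes used by the test and acceptance runs

Unit and property tests run on 60–120-protein studies; the recovery sweeps
use 100 seeded small studies (branch classification), 100 random networks
of ≤ 50 metabolites (extraction equivalence), all 46,375 2×2 tables with
n ≤ 30 (exact-test equivalence), and 500-reaction studies for the
correlation brackets — sizes at which every oracle is exhaustive or the
sampling bound is a ≥ 3σ margin, while the whole suite stays in the
half-minute range.

## Known limitations

Branch scores bound capacity, not realized flux; no flux inference is
attempted. Enrichment uses raw p-values by default, matching the
significance convention of small branch sets; for large pathway collections
enable the BH flag. The canonical glycolysis definition is one defensible
reconstruction among several. Real-database branch counts depend on the
network reconstruction release and are not reproducible from synthetic
data; the pipeline reports whatever the supplied network yields.
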