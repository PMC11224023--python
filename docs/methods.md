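# Methods

`nimx` re-implements, as a tested pipeline, the computational core of a
neuroimmune-interactome study of inflammatory pain: skin immune cells
profiled by scRNA-seq after three inflammatory insults (zymosan
injection, surgical incision, UV burn) at 4/24/48 h signal to dorsal
root ganglion (DRG) sensory neurons, whose subtype-resolved receptor
repertoires come from steady-state snRNA-seq. This note documents the
models, parameters and numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Gene role sets

Four symbol sets gate interactome assembly, each from its own snapshot
dialect:

* **receptors** — proteins flagged `receptor` in a CellPhoneDB-style
  protein table (one row per UniProt accession; conflicting duplicate
  flags are an error);
* **ligands** — source participants of interactions with a well-defined
  consensus direction in the filtered interaction table, minus known
  receptors;
* **enzymes** — catalog members carrying at least one EC class, with
  kinases and phosphatases removed (intracellular signaling steps, not
  intercellular messengers);
* **ion channels** — a curated list minus any overlap with receptors or
  ligands.

The interaction table (OmniPath-style TSV) is filtered to rows with
curation effort > 0, human taxon (9606), the `ligrecextra` subset tag,
and at least one of ten admitted resource labels (CellPhoneDB,
Guide2Pharma, HPMR, ICELLNET, Kirouac2010, CellTalkDB, CellChatDB,
connectomeDB2020, Ramilowski2015, talklr; exact, case-sensitive
matching). The four predicates commute, so filter order is immaterial;
duplicate (source, target) rows collapse keeping the maximum curation
effort and the union of resource labels. Heteromeric complexes are out
of scope: only single-protein rows are consumed.

## Interactome assembly

Three modalities, deduplicated on (sender gene, receiver gene,
modality) — the same gene pair may appear once per modality:

1. **ligand → receptor**: directed filtered rows whose endpoints pass
   the role gates. The table's own curation stands as structured
   evidence when no statement-level evidence is indexed.
2. **enzyme → product → receptor**: `controls-production-of` SIF triples
   whose controller is in the enzyme set define each enzyme's product
   set; Activation/Complex statements linking a product to a receptor
   then yield one record per (enzyme, receptor), carrying the
   intermediate product and the statement's evidence.
3. **ligand/product → ion channel**: statements linking a ligand or an
   enzyme product to a channel, retained only when supported by a
   structured database or by at least two text-mined sentences. This
   evidence filter applies to the channel modality only; ligand-receptor
   records inherit the interaction table's curation.

Statement orientation: Activation statements count only in their stated
subject→object direction; Complex statements are undirected and oriented
by role (ligand/product as sender). Evidence kinds are decided by the
statement's `source_api` against a configurable structured-source list;
a text-mining evidence item contributes one supporting sentence when it
carries text.

Human records expand to mouse over an HGNC-style ortholog table as the
Cartesian product of each endpoint's orthologs; records with any
unmapped endpoint are dropped and reported, every mouse record
back-references its human source, and mouse casing follows the table
verbatim. The export is a headered TSV keyed for stable sorting; the
evidence list is serialized as JSON in `evidence_summary` so that
export → import is lossless, and assembly is deterministic down to
bytes.

## Single-cell pipeline

**QC.** Doublet-flagged cells are removed first. Per sample, cells whose
log10 library size or log10 feature count falls outside mean ± 1.96 sd
(computed over that sample's singlets) are removed, as are cells with
mitochondrial fraction > 0.05. The 95% interval is taken on the log10
scale per sample; the source protocol states only "95% confidence
interval", and the per-sample log-scale reading is the standard one.
Samples with fewer than three singlets skip the interval (undefined)
with a warning. The report tallies removals by reason; a cell violating
several rules is counted under each.

**Normalization.** Counts per cell are scaled to 10,000 (CP10K) and
log1p-transformed (scanpy); raw counts are retained in a layer.

**Differential expression.** FindMarkers-convention Wilcoxon rank-sum on
the normalized values: a gene is tested only if the larger expressing
fraction of the two groups reaches `min.pct` and the Seurat-style fold
change log2((mean expm1 + 1)/(mean expm1 + 1)) reaches the threshold
(immune compartment 0.25 / 0.10; neuron compartment 0.8 / 0.25).
The two-sided p-value is P(|W − μ| ≥ |w_obs − μ|) under random group
assignment: exhaustively enumerated for n₁+n₂ ≤ 14 (rank sums land on a
0.5 grid, so the comparison carries a 1e-9 slack and is exact), and a
tie-corrected normal approximation without continuity correction above
that, which matches `scipy.stats.mannwhitneyu(method="asymptotic",
use_continuity=False)`. Benjamini–Hochberg runs over the tested genes;
significance is adjusted p < 0.05. Contrasts compare (cell type,
condition, timepoint) against contralateral cells of the same type and
timepoint, with cells pooled across replicates.

**DiVenn classification.** Each gene significant in ≥ 1 of ≥ 2 contrasts
is assigned to the Venn region of contrasts where it is significant and
colored `up`/`down` when its direction agrees across them, `divergent`
otherwise — a partition with exactly one region and color per gene.

**Proportions.** Per-sample cell-type fractions (summing to one) and
unweighted means across replicate samples per condition × timepoint,
with absent types counted as zero.

## Communication scoring

For interactome record r, sender type s and receiver type t, the
communication probability is the Hill-saturated mass-action score

    P(r, s, t) = L·R / (kh + L·R),  kh = 0.5,

with L and R the 25%-per-tail trimmed means of the per-cell CP10K
(non-log) values of the sender and receiver genes. For enzyme-mediated
records L is the enzyme transcript — the metabolite itself is
unmeasured in scRNA-seq and the transcript is the only available proxy;
for channel records R is the channel transcript. The trimmed mean is
zero unless more than ~25% of cells express the gene, which acts as a
built-in minimum-expression gate.

Significance: cell-type labels are shuffled globally across cells
n_perm = 100 times and p = (1 + #{P_perm ≥ P_obs}) / (1 + n_perm), so
p-values live on the grid k/(n_perm+1) and are seed-reproducible.
Receiver-side DRG-neuron profiles are fixed summarized matrices
(steady-state, transcriptionally unresponsive to acute injury), so they
do not permute; a sidecar file carries per-subtype nucleus counts for
the cell filter. BH adjustment runs over the triples with nonzero
observed probability within one condition × timepoint dataset —
zero-probability triples are untestable and keep p_adj = 1 — and a
triple is significant when p_adj ≤ 0.05 and both cell types have ≥ 10
cells. Aggregate networks sum significant probabilities per
sender × receiver pair; the injury comparison partitions significant
interaction keys by the set of conditions (at each injury's peak-pain
timepoint T_max: zymosan 4 h, incision 24 h, UV burn 48 h) in which they
appear.

## Synthetic data

**Fixture knowledge bases** write all seven snapshot dialects with
planted survivors (e.g. THBS1→CD47, OSM→IL6ST, PTGS2→PGE2→PTGER4,
ALDH3A2→β-alanine→MRGPRD, NGF→TRPV1) and planted violations (zero
curation effort, mouse-taxon rows, wrong subset, disallowed resources,
undirected rows, kinase "enzymes", role-overlapping channels,
one-sentence channel statements, reversed Activation statements,
orphaned products, unmapped and one-to-two orthologs), plus a manifest
of every expected survivor kept by generator-side bookkeeping — never by
running the assembler. Tests compare the assembler against both the
manifest and an independent brute-force enumeration.

**Expression data** cover 12 condition × timepoint groups (three
injuries × 4/24/48 h plus contralateral controls at each timepoint), 2
replicates × 600 cells × 800 genes by default, ~15 immune cell types
with negative-binomial counts (mean, dispersion θ = 2; dropout arises
from low means, no extra zero inflation), mild per-cell library-size
jitter, marker-gene structure, and planted truths: neutrophil and
recruited-macrophage influx multipliers peaking at each injury's T_max;
DE shifts (e.g. Thbs1 up in macrophages at peak-pain timepoints, C1qa
down); an 8× sender-restricted ligand enrichment per condition as the
communication plant; and QC violations (doublets, high-mito, extreme
library sizes) labeled per cell. Neuron profiles give the nine DRG
subtypes (cLTMR1, NF1–3, NP, p_cLTMR2, PEP1/2, SST) subtype-restricted
receptor repertoires (Osmr only in SST, Kit only in PEP1, Ifngr2 only in
cLTMR1, ...); one subtype is kept below ten nuclei to exercise the cell
filter. Generation is fully deterministic per seed.

Two focused benchmarks isolate single properties:

* the **DE benchmark** (200 cells/group, 24 planted of 500 genes,
  |log2FC| ∈ [1, 1.6]) alternates planted signs so library composition
  stays balanced between groups — otherwise per-cell normalization
  imparts a real fold change onto the unplanted genes and the "null"
  false-positive rate measures that artifact instead of the test;
* the **communication benchmark** uses the planted communication plan as
  the only enrichment (empty DE plan), so recovered pairs are
  attributable solely to the planted signal. Receptor repertoires are
  laid out so that no two interactome records co-locate on the same
  sender–receiver cell pair; a single chance-elevated record is then
  bounded below the planted entry (receiver saturation 3 vs 8), making
  the network-maximum readout identify the planted pair rather than an
  artifact of record stacking.

What passing these benchmarks does **not** show: robustness to batch
effects, ambient RNA, doublet-score errors, annotation noise or
transcriptome-wide co-expression structure — none of which the generator
emulates. The printed role-set and interactome sizes of the original
resource (941/560/2,881/293; 2,827 + 6,868 + 177 = 9,872) depend on
pinned external snapshots and are deliberately not reproduced; the
package reproduces the rules, arithmetic and filters that produced them.

## Numerical and degenerate-input choices

* Exact Wilcoxon enumeration is used through n₁+n₂ = 14 (≤ 3,432
  assignments, vectorized as a 0/1 matrix product); constant genes get
  p = 1 (zero permutation variance).
* BH adjusted values are clamped to be ≥ the raw p.
* Communication p for a zero-probability triple is 1 by the +1 rule
  (every permutation ties or exceeds).
* QC on a sample with < 3 singlets passes the sample through with a
  warning; zero-library cells fail normalization loudly.
* All written artifacts (role JSON, interactome TSVs, DE tables,
  networks, comparison JSON, run manifest) use sorted keys and stable
  sorts; two runs with one seed are byte-identical, verified by SHA-256
  in the run manifest.

## Problem sizes used by the test suite and acceptance script

Fixture knowledge bases are ~60 interaction rows / ~30 statements;
assembler–oracle equivalence is checked over 20 random seeds. Wilcoxon
exactness uses 1,000 random small-sample datasets. The DE benchmark
averages 5 seeds; null calibration scores 500 independent-gene triples
at n_perm = 100; communication recovery runs the full 12-group benchmark
once per seed; end-to-end reproducibility runs the default synthetic
configuration twice. These sizes keep the full suite and the acceptance
script each within a few minutes on one CPU while leaving every
statistical check adequately powered.
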