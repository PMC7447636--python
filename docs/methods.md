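# Methods

This note records the models, conventions and numerical choices behind
fusionscope, and what the synthetic cohorts do and do not establish about
behavior on real data.

## Fusion assembly and frame prediction

Gene models are GTF transcripts with 1-based inclusive coordinates; the
CDS includes the stop codon, so its length is divisible by 3. One canonical
transcript is kept per gene — the one with the longest CDS, ties broken by
transcript id. This keeps deduplication keys stable; tools that iterate all
isoforms will report different unique-fusion counts, which is expected.

A breakpoint call is resolvable only if the 5' coordinate is a donor exon
boundary (transcript-orientation exon end) and the 3' coordinate an
acceptor boundary (exon start) of the canonical transcripts. Unresolvable
and same-gene calls are retained with a status flag and excluded from the
protein set. The fused transcript is the 5' transcript through the donor
boundary concatenated with the 3' transcript from the acceptor onward.

Frame logic: with `p` = coding nucleotides 5' of the junction and `q` = the
acceptor's offset into the 3' CDS, the fusion is in-frame iff
`p ≡ q (mod 3)`. The same congruence covers acceptors upstream of the 3'
CDS start (negative `q`). Translation runs from the 5' start codon to the
first stop; the frame *call* is phase-based, so a rare stop codon formed at
the junction leaves the call "in-frame" while the protein itself truncates
(aa3 = 0, never protein-producing). The junction-spanning codon is
attributed to aa3 — a tie-break the underlying procedure leaves open; it is
fixed here and tested explicitly. "Both genes contribute over 30 aa" is
read strictly: protein-producing ⇔ in-frame ∧ aa5 ≥ 31 ∧ aa3 ≥ 31.

A junction upstream of the 5' CDS start is classified as a promoter swap
(intact 3' gene under the 5' promoter) and predicts no fusion protein.

Two deduplication passes exist because they serve different questions:
the full key (gene ids, biotypes, breakpoints, frame effect, protein
sequence) defines *unique fusions* for counting; a second pass on
(gene pair, protein sequence) defines the unit for domain-level analyses.
Clinical summaries and DE grouping instead work on fusion–sample
occurrences (unique fusion × carrying sample), since a recurrent fusion
contributes every sample that carries it.

## Clinical harmonization

Stage strings are matched case-insensitively; trailing sub-stage letters
with optional numerals are stripped (`Stage IIA → Stage II`,
`Stage IIIC1 → Stage III`); `Stage 0`, `Stage X`, `I/II NOS` and anything
outside Stage I–IV map to absent. Topography codes truncate at the dot
(`C56.9 → C56`); non-conforming codes become absent with a warning. The
barcode join key is the first three dash-delimited fields. Breakpoints are
binned into twenty 5% contig intervals via
`floor(20·(pos−1)/L)` clamped to `[0, 19]` — the edge rule is ours, chosen
for an exact partition. Stage-group counts use unique fusion–sample pairs;
groups with < 10 samples are flagged, not dropped. A project with zero
protein-producing fusions reports no PK/TF proportion rather than zero.

## Domain architecture

Intactness is exact full-length substring occurrence of the wild-type
domain sequence in the fusion protein — junction-spanning matches count,
a single-residue truncation does not. Each wild-type instance counts once
per fusion regardless of how many positions match; the side (5'/3') is
assigned from the first match position relative to aa5. Specificity uses
the intact copies within the analyzed fusion set as the denominator and a
threshold of ≥ 0.95 — the strict-inequality variant would differ only at
exactly 19/20, which is unit-tested. Copies are attributed to PK/TF by the
wild-type protein carrying the instance.

## Interactome and pathway mapping

An interaction edge supports an interactor only if it is both a physical
type (physical association / direct interaction / association) and
experimentally detected (not in-silico/inference/text-mining); the
vocabularies are module constants and can be remapped. Edges are
undirected, canonicalized `a ≤ b`; duplicate pairs keep the best-supported
record; self-loops are dropped with a logged count. The interactor set of a
fusion is the union of both partners' supported neighbors minus the
partners.

Root distances in the pathway DAG are computed with multi-source Dijkstra
from the roots at unit weight, which is exactly BFS; the equivalence is
asserted over random DAGs rather than assumed. Per-pathway burden is
emitted in both published senses — the count of fusions with ≥ 1 annotated
interactor, and the summed per-protein load — and per-project
normalization (max = 1 within a project) is computed from the summed load.

## Differential expression

The test is the standard RNA-seq NB-GLM contract implemented in closed
form so the resampling procedure stays affordable (~3 ms per 1,000-gene
test; a model-fitting implementation would make 1,000 replicates per pair
impractical):

* size factors: median-of-ratios over genes positive in all samples, with
  a library-size fallback for degenerate matrices;
* group means: `q̂_g = Σ counts / Σ size factors` per condition;
* dispersion (`var = μ + α μ²`): pooled within-group moment estimates,
  a least-squares `α(μ) = a0 + a1/μ` trend, and log-space shrinkage of
  gene estimates toward the trend with a prior weight of 10 equivalent
  observations — at 5v5 roughly an even blend, chosen so that single-gene
  noise does not dominate at the sample sizes the procedure actually sees;
* Wald statistic from the NB Fisher information
  `I = Σ_j μ_j/(1+αμ_j)` per condition, referred to a t distribution with
  residual degrees of freedom (n₁+n₂−2): with estimated dispersions the
  normal reference is visibly anticonservative at n = 10 (observed
  false-discovery proportions above the nominal level), and the t reference
  restores calibration with negligible power cost;
* Benjamini–Hochberg over genes with nonzero counts; all-zero genes are
  excluded from the test and the denominator;
* log2 fold changes use a pseudocount of 0.5 on normalized means, which
  bounds the estimate without dropping genes and makes label-swap
  antisymmetry exact.

Replication draws a fresh equal-size control set per run (uniform, without
replacement, stream seeded by (master seed, replicate index) so runs are
order-independent). A gene is reported when significant in ≥ 50% of runs —
our resolution of an ambiguity in whether filtering applies per run or
after averaging; the fraction is configurable. Reported means are averaged
over the runs in which the gene was tested and the fold change is
recomputed from the averaged means. Because the case samples are fixed,
only the control-side averages fluctuate across reruns; the 1/√n_reps
convergence diagnostic therefore applies to the averaged control mean.

Pathway z-scores use lowest-level (leaf) terms only:
`z = (n_up − n_down)/√(n_up + n_down)`, with |z| > 7.5 flagged. Pathways
with no significant genes are omitted.

Samples may belong to several case groups (a sample can carry fusions of
two qualifying pairs); the control pool excludes any sample with a PK/TF
protein-producing fusion, so pools are automatically disjoint from every
case group. A group whose control pool is smaller than its case count is
skipped with a warning — the equal-size draw is undefined there.

## Synthetic cohorts

The generator emulates a pan-cancer fusion survey at desk scale: one
multi-exon gene per contig (valid ORF, 180–320 codons, 3–6 exons, both
strands), exon-boundary breakpoints strictly inside both CDSs with ≥ 96 nt
of 5' and ≥ 99 nt of 3' coding sequence, an in-frame fraction of 0.69
(the share of in-frame calls in large pan-cancer sets), PK labels on 8%
and TF labels on 10% of genes, a preferential-attachment interaction
network with a configurable non-physical edge fraction, a leveled rooted
pathway DAG, dirty clinical strings, and NB counts
(`var = μ + 0.1 μ²`, log-uniform baselines ≈ 20–3000). A few recurrent
"hot" gene pairs (biased toward PK/TF partners, as recurrent fusions are)
give downstream grouping multi-sample pairs to work with. Planted
expression effects go to the most recurrent qualifying pairs with disjoint
sample sets, preferring pairs with ≥ 3 case samples (a 2v2 comparison has
essentially no power), and never to more than ~20% of the gene universe —
median-of-ratios normalization assumes most genes are unchanged, and a
majority shift is indistinguishable from library size by design, not by
defect.

Ground truth (frame effects, per-partner aa contributions, fused proteins,
domain classes, planted fold changes) is computed by independent arithmetic
on the constructed sequences, never by calling the pipeline.

What passing on synthetic data does **not** show: robustness to intra-exon
breakpoints, isoform ambiguity, alignment artifacts in real fusion calls,
GC or length biases in counts, batch structure, or annotation
incompleteness in real interactome/pathway snapshots. Cohort-scale counts
from the original TCGA-scale analysis depend on those inputs and are not
reproduced here; the package asserts the rules and calibration properties
instead.

## Problem sizes and determinism

Default exercised sizes: cohorts of 60–100 genes, 40–60 samples, 80–600
fusions; DE calibration and recovery at 1,000 genes, 5v5, dispersions 0.1,
with 20–160 replicates — sizes at which every statistical property is
measurable with comfortable margins. All generators and the pipeline are
pure functions of (spec, seed); identical runs are byte-identical (the run
manifest deliberately records no timestamps).
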