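# fusionscope

Characterization of protein-kinase (PK) and transcription-factor (TF) gene
fusions in cancer cohorts: reading-frame prediction for fusion transcripts,
full-length domain retention on the predicted fusion proteins, maximal
foreseeable interactor sets mapped onto a pathway hierarchy, and a
replicated random-control differential-expression procedure for
fusion-pair sample groups.

## Who this is for

Computational cancer biologists working with fusion calls (breakpoint
tables from detection tools run on RNA-seq cohorts such as TCGA) who want
to go beyond the call list: which fusions can actually produce a chimeric
protein, which functional domains survive the junction, what the fused
proteins could plausibly interact with, and whether samples carrying a
given fusion pair show a distinct expression program. Every stage also runs
on a built-in synthetic cohort with known ground truth, so the whole
pipeline is testable end to end without any external download.

## The model in brief

**Frame prediction.** A fusion joins the 5' portion of one transcript,
cut at an exon boundary, to the 3' portion of another. Translation starts
at the 5' partner's start codon; with *p* coding nucleotides contributed by
the 5' partner and the acceptor boundary sitting *q* nucleotides into the
3' partner's CDS, the fusion is **in-frame** iff *p ≡ q (mod 3)* — the
downstream wild-type peptide is then reproduced verbatim. A fusion is
**protein-producing** iff it is in-frame and each partner contributes
strictly more than 30 aa (aa5 ≥ 31 and aa3 ≥ 31). The junction-spanning
codon counts toward the 3' contribution.

**Domain retention.** A wild-type Pfam-style domain instance is *intact* in
a fusion protein iff its complete amino-acid sequence occurs unmodified in
the predicted protein. A domain accession is *PK-specific* when ≥ 95% of
its intact copies sit on kinase sides (TF analogous).

**Interactors and pathways.** The maximal foreseeable interactor set of a
fusion is the union of both partners' experimentally validated physical
interactors, minus the partners. Pathway terms form a rooted DAG; each
term's depth is its shortest unit-weight distance to a root (Dijkstra,
equivalent to BFS at unit weight).

**Differential expression.** Samples carrying a fusion pair with an intact
PK-/TF-specific domain form a case group; samples whose protein-producing
fusions are all non-PK/TF form the control pool. For each pair, an equal
number of controls is redrawn and a negative-binomial Wald test
(median-of-ratios size factors, trend-shrunk dispersions,
Benjamini–Hochberg q-values) is run; the cycle repeats (1,000× at full
scale), genes significant in ≥ 50% of runs are reported with run-averaged
means, and per-pathway over/underexpression is condensed to

    z = (n_up − n_down) / sqrt(n_up + n_down)

over lowest-level pathway terms.

## Worked example

```sh
fusionscope demo --seed 7 -o demo_out
```

generates a 100-gene, 60-sample synthetic cohort with 150 breakpoint calls
and two planted fusion-pair expression effects, writes all input files
(GTF, FASTA, call/domain/clinical/interaction/pathway TSVs, per-sample
HTSeq-count files) under `demo_out/inputs/`, runs all five stages, and
prints the manifest:

```json
"annotate": { "n_calls": 150, "n_pk_tf": 58, "n_protein_producing": 88, "n_unique_fusions": 124 },
"domains":  { "n_domain_calls": 126, "n_intact": 58, "n_pk_specific": 2, "n_tf_specific": 3,
              "mean_domains_per_fusion": 0.6591 },
"network":  { "n_fusions_with_interactors": 88, "n_pathways": 36, "n_supported_edges": 161 },
"de":       { "n_pair_groups": 3, "n_de_genes": 14, "n_pathway_z_rows": 6 }
```

Reading: of 150 calls, 124 are unique fusions; 88 are predicted to produce
a chimeric protein (in-frame, both partners > 30 aa) and 58 involve a PK or
TF partner. 58 wild-type domains survive their junctions intact, and 5
accessions are PK-/TF-specific. Three fusion-pair case groups qualify for
the replicated DE procedure; one of them carries a planted 4-fold effect,
and its table `demo_out/results/de_GENE70-GENE91.tsv` recovers it:

```
gene_id    avg_basemean  avg_case_mean  avg_control_mean  log2fc  q       n_runs_significant  direction
SYNG00000  158.2         240.1          76.7              1.64    0.043   17                  over
SYNG00023  1828.3        2945.4         683.8             2.11    0.031   17                  over
```

The planted genes come back with log2 fold changes near the planted value
of 2, significant in 17 of 20 replicate runs; the two unplanted pair groups
correctly report nothing.

The same stages are available individually (`fusionscope annotate`,
`cohort`, `run --config run.cfg`, `validate`) — see `--help`.

As a library, the DE stage is exposed statsmodels-style:

```python
from fusionscope import FusionPairDE, DEConfig
model = FusionPairDE(counts, group, DEConfig(n_reps=1000, seed=17))
results = model.fit()
print(results.summary())
z = results.pathway_z(annotations, dag.lowest_level_terms())
```

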