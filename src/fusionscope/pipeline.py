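"""End-to-end orchestration: annotate -> cohort -> domains -> network -> de.

A run is driven by a :class:`PipelineConfig` (paths, thresholds, seed); each
stage writes its tables under the output directory and contributes row
counts to a manifest. Stage outputs are pure functions of (inputs, config,
seed): rerunning an identical config is byte-identical. The manifest
deliberately records no timestamps so that two runs can be diffed directly.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io_formats as io
from . import __version__
from .cohort_clinical import bin_breakpoints, join_clinical, summarize_by_project_stage
from .differential_expression import (
    ConfigError,
    DEConfig,
    build_groups,
    pathway_zscores,
    replicate_and_average,
)
from .domain_architecture import (
    call_domains,
    classify_specificity,
    instances_from_table,
    summarize_domains,
)
from .fusion_annotation import annotate_calls, deduplicate, deduplicate_for_domains
from .interactome_pathways import PathwayDAG, census_enrichment, interactor_sets, pathway_loads, root_distances

logger = logging.getLogger(__name__)

STAGES = ("annotate", "cohort", "domains", "network", "de")


@dataclass
class PipelineConfig:
    gtf: Path
    genome_fasta: Path
    calls: Path
    pk_list: Path
    tf_list: Path
    domains: Path
    interactions: Path
    pathway_edges: Path
    pathway_annotations: Path
    clinical: Path
    counts_dir: Path
    outdir: Path
    census: Path | None = None
    aa_min: int = 30
    specificity: float = 0.95
    q: float = 0.05
    z_highlight: float = 7.5
    n_reps: int = 1000
    seed: int = 0

    _PATH_FIELDS = (
        "gtf", "genome_fasta", "calls", "pk_list", "tf_list", "domains",
        "interactions", "pathway_edges", "pathway_annotations", "clinical", "counts_dir",
    )

    def __post_init__(self) -> None:
        for name in self._PATH_FIELDS + ("outdir",):
            setattr(self, name, Path(getattr(self, name)))
        if self.census is not None:
            self.census = Path(self.census)
        if not 0 < self.q < 1:
            raise ConfigError(f"q={self.q} outside (0, 1)")
        if not 0 < self.specificity <= 1:
            raise ConfigError(f"specificity={self.specificity} outside (0, 1]")
        if self.aa_min < 0 or self.n_reps < 1 or self.z_highlight < 0:
            raise ConfigError("aa_min, n_reps, z_highlight out of range")

    def validate_paths(self) -> None:
        for name in self._PATH_FIELDS:
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"input path for '{name}' does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key/value config with [paths], [thresholds], [run] sections."""
        cp = configparser.ConfigParser()
        cp.read(path)
        kw: dict = {}
        for key, val in cp.items("paths"):
            kw[key] = val
        for key, val in cp.items("thresholds") if cp.has_section("thresholds") else []:
            kw[key] = float(val) if "." in val else int(val)
        for key, val in cp.items("run") if cp.has_section("run") else []:
            kw[key] = int(val) if val.lstrip("-").isdigit() else val
        kw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    config.validate_paths()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in config._PATH_FIELDS
            if Path(getattr(config, name)).is_file()
        },
    }

    # --- annotate ----------------------------------------------------------
    models = io.read_gtf(config.gtf)
    contigs = io.read_fasta(config.genome_fasta)
    calls = io.read_fusion_calls(config.calls)
    pk = io.read_gene_list(config.pk_list)
    tf = io.read_gene_list(config.tf_list)
    annotated = annotate_calls(calls, models, contigs, pk, tf)
    unique = deduplicate(annotated)
    # per-sample occurrences: identical calls collapse within a sample only;
    # clinical summaries and DE grouping need every carrying sample
    from .fusion_annotation import FUSION_KEY_COLUMNS

    per_sample = annotated.drop_duplicates(
        subset=FUSION_KEY_COLUMNS + ["sample_barcode"]
    ).reset_index(drop=True)
    unique.to_csv(out / "fusions.tsv", sep="\t", index=True, index_label="fusion_index")
    proteins_fa = {
        f"fusion_{i}": row["protein"]
        for i, row in unique.iterrows()
        if row["protein_producing"]
    }
    io.write_fasta(proteins_fa, out / "fusion_proteins.fa")
    manifest["stages"]["annotate"] = {
        "n_calls": int(len(calls)),
        "n_unique_fusions": int(len(unique)),
        "n_protein_producing": int(unique["protein_producing"].sum()),
        "n_pk_tf": int(unique["category"].isin(("PK", "TF", "PK-TF")).sum()),
    }

    # --- cohort ------------------------------------------------------------
    clinical = io.read_clinical(config.clinical)
    joined = join_clinical(unique, clinical)
    per_sample_joined = join_clinical(per_sample, clinical)
    per_sample_joined.to_csv(
        out / "fusions_clinical.tsv", sep="\t", index=True, index_label="occurrence_index"
    )
    stage_df, project_df = summarize_by_project_stage(per_sample_joined, clinical)
    stage_df.to_csv(out / "stage_summary.tsv", sep="\t", index=False)
    project_df.to_csv(out / "project_summary.tsv", sep="\t", index=False)
    contig_lengths = {name: len(seq) for name, seq in contigs.items()}
    bins = bin_breakpoints(per_sample_joined, contig_lengths)
    bins.to_csv(out / "breakpoint_bins.tsv", sep="\t", index=False)
    manifest["stages"]["cohort"] = {
        "n_stage_groups": int(len(stage_df)),
        "n_projects": int(len(project_df)),
        "n_binned_breakpoints": int(bins["count"].sum()),
    }

    # --- domains -----------------------------------------------------------
    wt_models = {m.gene_id: m for m in models}
    proteins = {g: m.protein_sequence(contigs) for g, m in wt_models.items()}
    instances = instances_from_table(io.read_domain_table(config.domains), proteins)
    dom_fusions = deduplicate_for_domains(joined[joined["protein_producing"]])
    domain_calls = call_domains(dom_fusions, instances)
    domain_calls.to_csv(out / "domain_calls.tsv", sep="\t", index=False)
    spec_df = classify_specificity(domain_calls, pk, tf, threshold=config.specificity)
    spec_df.to_csv(out / "domain_specificity.tsv", sep="\t", index=False)
    dom_summary = summarize_domains(domain_calls, dom_fusions, spec_df)
    manifest["stages"]["domains"] = {
        "n_domain_calls": int(len(domain_calls)),
        "n_intact": int(domain_calls["intact"].sum()),
        "n_pk_specific": int((spec_df["class"] == "PK-specific").sum()),
        "n_tf_specific": int((spec_df["class"] == "TF-specific").sum()),
        "mean_domains_per_fusion": round(float(dom_summary["mean_domains_per_fusion"]), 4),
    }

    # --- network -----------------------------------------------------------
    edges = io.read_interactions(config.interactions)
    dag = PathwayDAG.from_tables(
        io.read_pathway_edges(config.pathway_edges),
        io.read_pathway_annotations(config.pathway_annotations),
    )
    pp = joined[joined["protein_producing"]]
    sets = interactor_sets(pp, edges)
    dists = root_distances(dag)
    pd.DataFrame(
        sorted(dists.items()), columns=["pathway_id", "root_distance"]
    ).to_csv(out / "pathway_root_distances.tsv", sep="\t", index=False)
    loads = pathway_loads(sets, dag, fusion_projects=pp["project"])
    loads.to_csv(out / "pathway_loads.tsv", sep="\t", index=False)
    manifest["stages"]["network"] = {
        "n_supported_edges": int(sum(e.is_supported for e in edges)),
        "n_fusions_with_interactors": int(sum(1 for s in sets.values() if s)),
        "n_pathways": int(len(loads)),
    }
    if config.census is not None and Path(config.census).exists():
        census = io.read_gene_list(config.census)
        enr = census_enrichment(sets, census, categories=pp["category"])
        manifest["stages"]["network"]["census_overall"] = (
            round(enr["overall"], 4) if enr["overall"] is not None else None
        )

    # --- de ----------------------------------------------------------------
    count_files = {
        p.name.split(".htseq")[0]: p for p in sorted(Path(config.counts_dir).glob("*.tsv"))
    }
    counts = io.read_htseq_counts(count_files)
    de_cfg = DEConfig(n_reps=config.n_reps, q_threshold=config.q, seed=config.seed)
    groups = build_groups(
        per_sample_joined, domain_calls, spec_df, list(counts.columns), key_table=joined
    )
    lowest = dag.lowest_level_terms()
    all_z = []
    n_de_genes = 0
    for group in groups:
        table = replicate_and_average(group, counts, de_cfg)
        safe = group.pair.replace("/", "_")
        table.to_csv(out / f"de_{safe}.tsv", sep="\t")
        n_de_genes += len(table)
        z = pathway_zscores(table, dag.annotations, lowest, z_highlight=config.z_highlight)
        z.insert(0, "pair", group.pair)
        all_z.append(z)
    all_z = [z for z in all_z if len(z)]
    zdf = (
        pd.concat(all_z, ignore_index=True)
        if all_z
        else pd.DataFrame(columns=["pair", "pathway_id", "n_up", "n_down", "z", "highlighted"])
    )
    zdf.to_csv(out / "pathway_zscores.tsv", sep="\t", index=False)
    manifest["stages"]["de"] = {
        "n_pair_groups": int(len(groups)),
        "n_de_genes": int(n_de_genes),
        "n_pathway_z_rows": int(len(zdf)),
        "n_highlighted": int(zdf["highlighted"].sum()) if len(zdf) else 0,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Demo on synthetic data
# ---------------------------------------------------------------------------


def write_synthetic_inputs(cohort, indir: Path) -> dict[str, Path]:
    """Serialize a generated cohort into the on-disk input formats."""
    indir = Path(indir)
    indir.mkdir(parents=True, exist_ok=True)
    io.write_gtf(cohort.models.models, indir / "genes.gtf")
    io.write_fasta(cohort.models.contigs, indir / "genome.fa")
    io.write_fusion_calls(cohort.calls, indir / "calls.tsv")
    io.write_gene_list(cohort.models.pk_genes, indir / "pk.tsv")
    io.write_gene_list(cohort.models.tf_genes, indir / "tf.tsv")
    io.write_domain_table(cohort.domains, indir / "domains.tsv")
    io.write_interactions(cohort.interactions, indir / "interactions.tsv")
    io.write_pathway_edges(cohort.pathway_edges, indir / "pathway_edges.tsv")
    io.write_pathway_annotations(cohort.annotations, indir / "pathway_annotations.tsv")
    io.write_clinical(cohort.clinical, indir / "clinical.tsv")
    counts_dir = indir / "counts"
    io.write_htseq_counts(cohort.counts, counts_dir)
    return {
        "gtf": indir / "genes.gtf",
        "genome_fasta": indir / "genome.fa",
        "calls": indir / "calls.tsv",
        "pk_list": indir / "pk.tsv",
        "tf_list": indir / "tf.tsv",
        "domains": indir / "domains.tsv",
        "interactions": indir / "interactions.tsv",
        "pathway_edges": indir / "pathway_edges.tsv",
        "pathway_annotations": indir / "pathway_annotations.tsv",
        "clinical": indir / "clinical.tsv",
        "counts_dir": counts_dir,
    }


def demo(
    seed: int,
    outdir: str | Path,
    n_genes: int = 100,
    n_samples: int = 60,
    n_fusions: int = 150,
    n_reps: int = 20,
) -> dict:
    """Generate a synthetic cohort, write its input files, run every stage."""
    from .synthetic_data import SyntheticCohortSpec, generate_all

    outdir = Path(outdir)
    spec = SyntheticCohortSpec(
        n_genes=n_genes, n_samples=n_samples, n_fusions=n_fusions, seed=seed
    )
    cohort = generate_all(spec)
    paths = write_synthetic_inputs(cohort, outdir / "inputs")
    config = PipelineConfig(
        outdir=outdir / "results", n_reps=n_reps, seed=seed, **paths
    )
    return run_pipeline(config)
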