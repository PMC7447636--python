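"""Synthetic cohort generator with known ground truth.

Every input the pipeline consumes — gene models and genome sequence, fusion
breakpoint calls, domain placements, PK/TF gene lists, an interaction
network, a rooted pathway hierarchy, dirty clinical strings, and
negative-binomial counts with planted fold-changes — is generated here so
that every downstream stage can be tested against a known answer without
downloading anything.

Design notes
------------
* One contig per gene; nothing downstream requires shared contigs.
* Breakpoints are placed only on exon boundaries, and only strictly inside
  the CDS of both partners, so frame arithmetic is exact.
* Ground truth is computed by independent arithmetic on the constructed
  sequences (a local codon loop), never by calling the annotation engine.
* Every generator is a pure function of (spec, seed): the same spec yields
  byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneModel

__all__ = [
    "InvalidSpecError",
    "SyntheticCohortSpec",
    "GroundTruth",
    "SyntheticModels",
    "SyntheticCohort",
    "generate_gene_models",
    "generate_fusion_cohort",
    "generate_domain_table",
    "generate_counts",
    "generate_network_and_pathways",
    "generate_all",
]


class InvalidSpecError(ValueError):
    """The cohort spec violates a documented precondition."""


_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)
_CODON_TABLE = {
    codon: aa
    for codon, aa in zip(
        [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"],
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}


def _translate_until_stop(seq: str) -> str:
    """Plain codon-loop translation; stops at the first stop or partial codon."""
    aas = []
    for i in range(0, len(seq) - 2, 3):
        aa = _CODON_TABLE[seq[i : i + 3]]
        if aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort.

    Defaults emulate the scale and composition of a TCGA-like fusion survey
    shrunk to desk size: ~0.69 of fusions in frame (the fraction of in-frame
    calls in large pan-cancer fusion sets), PK labels on 8% and TF labels on
    10% of genes (so roughly a fifth to a third of fusions involve a PK or
    TF partner, as in pan-cancer cohorts), log-uniform baseline expression
    between ~20 and ~3000 counts, and a shared NB dispersion of 0.1
    (variance = mu + d*mu^2).
    """

    n_genes: int = 60
    n_samples: int = 60
    n_fusions: int = 150
    frac_inframe: float = 0.69
    frac_pk: float = 0.08
    frac_tf: float = 0.10
    nb_mean_log_range: tuple[float, float] = (3.0, 8.0)
    nb_dispersion: float = 0.1
    planted_pairs: tuple[tuple[str, tuple[str, ...], float], ...] = ()
    seed: int = 0
    # cohort texture
    recurrent_pair_fraction: float = 0.3
    n_recurrent_pairs: int = 3
    duplicate_call_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes <= 1:
            raise InvalidSpecError(f"n_genes must be >= 2, got {self.n_genes}")
        if self.n_fusions < 0:
            raise InvalidSpecError("n_fusions must be non-negative")
        for name in ("frac_inframe", "frac_pk", "frac_tf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name}={v} outside [0,1]")
        if self.frac_pk + self.frac_tf > 1.0:
            raise InvalidSpecError("frac_pk + frac_tf must be <= 1")
        if self.nb_dispersion <= 0:
            raise InvalidSpecError("nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """The generator's record of what it planted, keyed independently of the pipeline."""

    frame_effect: dict[int, str] = field(default_factory=dict)
    aa5: dict[int, int] = field(default_factory=dict)
    aa3: dict[int, int] = field(default_factory=dict)
    protein: dict[int, str] = field(default_factory=dict)
    domain_class: dict[str, str] = field(default_factory=dict)
    planted_lfc: dict[tuple[str, str], float] = field(default_factory=dict)
    nonphysical_edges: set[tuple[str, str]] = field(default_factory=set)
    case_samples: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class SyntheticModels:
    models: list[GeneModel]
    contigs: dict[str, str]
    proteins: dict[str, str]
    pk_genes: set[str]
    tf_genes: set[str]

    def by_gene(self) -> dict[str, GeneModel]:
        return {m.gene_id: m for m in self.models}


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _build_gene(rng: np.random.Generator, idx: int) -> tuple[GeneModel, str]:
    n_codons = int(rng.integers(180, 320))  # includes the stop codon
    cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2)) + str(
        rng.choice(np.array(_STOPS))
    )
    u5 = int(rng.integers(12, 60))
    u3 = int(rng.integers(12, 60))
    tx = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
    cds_len = 3 * n_codons

    # exon cuts strictly inside the CDS, leaving >=100 nt coding on each side
    n_exons = int(rng.integers(3, 7))
    lo, hi = u5 + 100, u5 + cds_len - 110
    w = (hi - lo) // (n_exons - 1)
    cuts = [lo + k * w + int(rng.integers(0, max(w - 30, 1))) for k in range(n_exons - 1)]
    bounds = [0] + cuts + [len(tx)]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]

    pad = 15
    pos = pad + 1
    plus_exons: list[tuple[int, int]] = []
    pieces = [_random_seq(rng, pad)]
    for i, el in enumerate(exon_lens):
        pieces.append(tx[bounds[i] : bounds[i + 1]])
        plus_exons.append((pos, pos + el - 1))
        pos += el
        if i < n_exons - 1:
            il = int(rng.integers(40, 150))
            pieces.append(_random_seq(rng, il))
            pos += il
    pieces.append(_random_seq(rng, pad))
    contig_seq = "".join(pieces)

    # CDS genomic intervals = transcript range [u5, u5+cds_len) mapped through exons
    plus_cds: list[tuple[int, int]] = []
    off = 0
    for (gs, ge), el in zip(plus_exons, exon_lens):
        a = max(u5, off)
        b = min(u5 + cds_len, off + el)
        if a < b:
            plus_cds.append((gs + (a - off), gs + (b - off) - 1))
        off += el

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        contig_seq = contig_seq.translate(comp)[::-1]
        L = len(contig_seq)
        flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
        plus_exons = sorted(flip(iv) for iv in plus_exons)
        plus_cds = sorted(flip(iv) for iv in plus_cds)

    gid = f"SYNG{idx:05d}"
    model = GeneModel(
        gene_id=gid,
        symbol=f"GENE{idx}",
        biotype="protein_coding",
        contig=f"ctg_{gid}",
        strand=strand,
        transcript_id=f"SYNT{idx:05d}",
        exons=tuple(plus_exons),
        cds=tuple(plus_cds),
    )
    return model, contig_seq


def generate_gene_models(spec: SyntheticCohortSpec) -> SyntheticModels:
    """Generate one multi-exon protein-coding gene per contig, plus PK/TF labels."""
    rng = np.random.default_rng([spec.seed, 1])
    models, contigs, proteins = [], {}, {}
    for i in range(spec.n_genes):
        m, seq = _build_gene(rng, i)
        models.append(m)
        contigs[m.contig] = seq
        proteins[m.gene_id] = _translate_until_stop(
            m.cds_sequence({m.contig: seq})
        )
    order = rng.permutation(spec.n_genes)
    n_pk = round(spec.frac_pk * spec.n_genes)
    n_tf = round(spec.frac_tf * spec.n_genes)
    pk = {models[i].gene_id for i in order[:n_pk]}
    tf = {models[i].gene_id for i in order[n_pk : n_pk + n_tf]}
    return SyntheticModels(models, contigs, proteins, pk, tf)


# ---------------------------------------------------------------------------
# Fusion calls
# ---------------------------------------------------------------------------


def _barcodes(rng: np.random.Generator, n: int) -> list[str]:
    alphabet = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"))
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        site = "".join(letters[rng.integers(0, 26, size=2)])
        part = "".join(alphabet[rng.integers(0, 36, size=4)])
        bc = f"TCGA-{site}-{part}"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _breakpoint_candidates(model: GeneModel) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """Valid (coding offset, tx offset, genomic pos) donors and acceptors.

    Donors keep >=96 nt of 5' coding sequence and stop short of the stop
    codon; acceptors leave >=99 nt of 3' coding sequence, so both partners
    can contribute >30 aa.
    """
    cs, cl = model.cds_tx_start, model.cds_length
    donors = [
        (off - cs, off, gpos)
        for off, gpos in model.donor_boundaries()
        if 96 <= off - cs <= cl - 6
    ]
    acceptors = [
        (off - cs, off, gpos)
        for off, gpos in model.acceptor_boundaries()
        if 0 <= off - cs and (cl - 3) - (off - cs) >= 99
    ]
    return donors, acceptors


def generate_fusion_cohort(
    smodels: SyntheticModels, spec: SyntheticCohortSpec
) -> tuple["pd.DataFrame", GroundTruth]:
    """Emit breakpoint calls at exon boundaries with a controlled in-frame fraction.

    Returns a fusion-call table (``io_formats.FUSION_CALL_COLUMNS``) and the
    ground truth keyed by row index.
    """
    import pandas as pd

    rng = np.random.default_rng([spec.seed, 2])
    barcodes = _barcodes(rng, spec.n_samples)
    by_gene = smodels.by_gene()
    gene_ids = sorted(by_gene)
    truth = GroundTruth()
    rows: list[dict] = []

    # recurrent gene pairs reused by a fraction of calls (one PK-, one TF-,
    # one mixed-partner pair when available) so downstream grouping has
    # multi-sample pairs to work with
    hot_pairs: list[tuple[str, str]] = []
    pools = [sorted(smodels.pk_genes), sorted(smodels.tf_genes), gene_ids]
    for k in range(spec.n_recurrent_pairs):
        pool = pools[k % 3] or gene_ids
        for _ in range(50):
            g5 = pool[rng.integers(0, len(pool))]
            g3 = gene_ids[rng.integers(0, len(gene_ids))]
            if g5 != g3 and _breakpoint_candidates(by_gene[g5])[0] and _breakpoint_candidates(by_gene[g3])[1]:
                hot_pairs.append((g5, g3))
                break

    i = 0
    attempts = 0
    while i < spec.n_fusions:
        attempts += 1
        if hot_pairs and rng.random() < spec.recurrent_pair_fraction:
            g5, g3 = hot_pairs[rng.integers(0, len(hot_pairs))]
        else:
            g5, g3 = rng.choice(gene_ids, size=2, replace=False)
        m5, m3 = by_gene[g5], by_gene[g3]
        donors, _ = _breakpoint_candidates(m5)
        _, acceptors = _breakpoint_candidates(m3)
        if not donors or not acceptors:
            continue
        want_inframe = rng.random() < spec.frac_inframe
        combos = [
            (d, a)
            for d, a in itertools.product(donors, acceptors)
            if ((d[0] % 3) == (a[0] % 3)) == want_inframe
        ]
        if not combos:
            # this gene pair cannot realize the drawn frame class; resample
            # the pair (give up only after many failed attempts)
            if attempts < 100 * spec.n_fusions:
                continue
            combos = list(itertools.product(donors, acceptors))
        (p5, off5, gpos5), (off3c, off3, gpos3) = combos[rng.integers(0, len(combos))]

        # independent ground-truth arithmetic on the constructed sequences
        cds5 = m5.cds_sequence(smodels.contigs)
        tx3 = m3.transcript_sequence(smodels.contigs)
        fused_coding = cds5[:p5] + tx3[off3:]
        prot = _translate_until_stop(fused_coding)
        aa5_t = min(p5 // 3, len(prot))
        effect = "in-frame" if (p5 % 3) == (off3c % 3) else "out-of-frame"

        idx = len(rows)
        rows.append(
            {
                "sample_barcode": barcodes[rng.integers(0, len(barcodes))],
                "gene5": g5,
                "gene3": g3,
                "contig5": m5.contig,
                "pos5": gpos5,
                "contig3": m3.contig,
                "pos3": gpos3,
            }
        )
        truth.frame_effect[idx] = effect
        truth.aa5[idx] = aa5_t
        truth.aa3[idx] = len(prot) - aa5_t
        truth.protein[idx] = prot

        # occasionally re-emit the identical fusion in another sample
        if rng.random() < spec.duplicate_call_fraction and i + 1 < spec.n_fusions:
            dup = dict(rows[idx])
            dup["sample_barcode"] = barcodes[rng.integers(0, len(barcodes))]
            j = len(rows)
            rows.append(dup)
            truth.frame_effect[j] = effect
            truth.aa5[j] = truth.aa5[idx]
            truth.aa3[j] = truth.aa3[idx]
            truth.protein[j] = prot
            i += 1
        i += 1

    df = pd.DataFrame(
        rows,
        columns=["sample_barcode", "gene5", "gene3", "contig5", "pos5", "contig3", "pos3"],
    )
    return df, truth


# ---------------------------------------------------------------------------
# Domain placements
# ---------------------------------------------------------------------------

_PK_DOMAINS = [("PF90001", "Pkinase_syn"), ("PF90003", "Pkinase_C_syn")]
_TF_DOMAINS = [("PF90002", "ZnF_C2H2_syn"), ("PF90004", "HLH_syn"), ("PF90005", "KRAB_syn")]
_SHARED_DOMAINS = [(f"PF910{i:02d}", f"Generic_dom_{i}") for i in range(5)]


def generate_domain_table(
    smodels: SyntheticModels, spec: SyntheticCohortSpec
) -> tuple["pd.DataFrame", dict[str, str]]:
    """Place domains on WT proteins with controlled PK/TF specificity.

    PK-pool accessions are placed only on PK-labelled genes (TF analogous),
    so their true specificity class is known; shared accessions land on any
    gene and are truly 'neither'. Returns (domain table, accession -> class).
    """
    import pandas as pd

    rng = np.random.default_rng([spec.seed, 3])
    rows = []
    for m in smodels.models:
        prot = smodels.proteins[m.gene_id]
        placements: list[tuple[str, str, int]] = []
        if m.gene_id in smodels.pk_genes:
            acc, name = _PK_DOMAINS[rng.integers(0, len(_PK_DOMAINS))]
            placements.append((acc, name, int(rng.integers(30, 61))))
        if m.gene_id in smodels.tf_genes:
            acc, name = _TF_DOMAINS[rng.integers(0, len(_TF_DOMAINS))]
            placements.append((acc, name, int(rng.integers(12, 31))))
        if rng.random() < 0.5:
            acc, name = _SHARED_DOMAINS[rng.integers(0, len(_SHARED_DOMAINS))]
            placements.append((acc, name, int(rng.integers(20, 41))))
        used: list[tuple[int, int]] = []
        for acc, name, length in placements:
            for _ in range(20):
                start = int(rng.integers(1, len(prot) - length))
                end = start + length - 1
                if all(end < s or start > e for s, e in used):
                    used.append((start, end))
                    rows.append(
                        {"protein": m.gene_id, "accession": acc, "name": name, "start": start, "end": end}
                    )
                    break
    classes = {acc: "PK-specific" for acc, _ in _PK_DOMAINS}
    classes.update({acc: "TF-specific" for acc, _ in _TF_DOMAINS})
    classes.update({acc: "neither" for acc, _ in _SHARED_DOMAINS})
    return pd.DataFrame(rows, columns=["protein", "accession", "name", "start", "end"]), classes


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def generate_counts(
    spec: SyntheticCohortSpec,
    sample_to_pair: dict[str, str | None],
    genes: list[str] | None = None,
) -> tuple["pd.DataFrame", GroundTruth]:
    """Draw a genes x samples NB count matrix with planted fold-changes.

    Variance model: var = mu + d * mu^2 with the spec's shared dispersion d.
    For each planted (pair, gene set, log2FC), gene means are multiplied by
    2**log2FC in the samples assigned to that pair. Pairs with fewer than two
    assigned samples raise :class:`InvalidSpecError` (mirrors the pipeline's
    two-file grouping rule).
    """
    import pandas as pd

    rng = np.random.default_rng([spec.seed, 4])
    if genes is None:
        genes = [f"SYNG{i:05d}" for i in range(spec.n_genes)]
    samples = sorted(sample_to_pair)
    pair_samples: dict[str, list[str]] = {}
    for s, p in sample_to_pair.items():
        if p is not None:
            pair_samples.setdefault(p, []).append(s)
    for pair, _genes, _lfc in spec.planted_pairs:
        if len(pair_samples.get(pair, [])) < 2:
            raise InvalidSpecError(f"planted pair {pair} has <2 assigned samples")
        unknown = set(_genes) - set(genes)
        if unknown:
            raise InvalidSpecError(f"planted genes not in gene universe: {sorted(unknown)}")

    lo, hi = spec.nb_mean_log_range
    base = np.exp(rng.uniform(lo, hi, size=len(genes)))
    mu = np.tile(base[:, None], (1, len(samples)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    truth = GroundTruth()
    for pair, pgenes, lfc in spec.planted_pairs:
        cols = [sample_idx[s] for s in sorted(pair_samples[pair])]
        for g in pgenes:
            mu[gene_idx[g], cols] *= 2.0 ** lfc
            truth.planted_lfc[(pair, g)] = lfc
        truth.case_samples[pair] = tuple(sorted(pair_samples[pair]))

    d = spec.nb_dispersion
    if d < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / d
        counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    return df, truth


# ---------------------------------------------------------------------------
# Network, pathway hierarchy, clinical strings
# ---------------------------------------------------------------------------

_DIRTY_STAGES = [
    "Stage I", "Stage IA", "Stage IB", "Stage II", "Stage IIA", "Stage IIB",
    "Stage III", "Stage IIIC1", "Stage IV", "Stage IVA",
    "Stage 0", "Stage X", "I/II NOS", "",
]
_TOPOGRAPHY = ["C56.9", "C50.1", "C34", "C18.9", "C71.0", "C16.2"]
_PROJECTS = ["SYN-BRCA", "SYN-THCA", "SYN-LAML"]


def generate_network_and_pathways(
    smodels: SyntheticModels,
    barcodes: list[str],
    spec: SyntheticCohortSpec,
    frac_nonphysical: float = 0.2,
    dag_depth: int = 4,
    n_pathways: int = 40,
) -> tuple[list, "pd.DataFrame", "pd.DataFrame", "pd.DataFrame", GroundTruth]:
    """Scale-free-ish interaction edges, a rooted pathway DAG with gene
    annotations, and a clinical table with dirty stage/topography strings.

    Returns (edges, pathway_edges, annotations, clinical, truth).
    """
    import networkx as nx
    import pandas as pd

    from .io_formats import _edge_from_fields

    rng = np.random.default_rng([spec.seed, 5])
    genes = sorted(smodels.by_gene())
    truth = GroundTruth()

    g = nx.barabasi_albert_graph(len(genes), m=2, seed=int(spec.seed % (2**31)))
    edges = []
    for u, v in sorted(g.edges()):
        a, b = sorted((genes[u], genes[v]))
        if rng.random() < frac_nonphysical:
            itype = ["colocalization", "genetic interaction"][rng.integers(0, 2)]
            method = "two hybrid"
            truth.nonphysical_edges.add((a, b))
        else:
            itype = sorted(["physical association", "direct interaction"])[rng.integers(0, 2)]
            method = ["two hybrid", "affinity chromatography", "pull down"][rng.integers(0, 3)]
        edges.append(_edge_from_fields(a, b, itype, method))

    # rooted DAG: every node's parents are on the previous level, so depth <= dag_depth
    root = "SYNPATH-ROOT"
    levels: list[list[str]] = [[root]]
    per_level = max(2, (n_pathways - 1) // dag_depth)
    pe_rows = []
    for lvl in range(1, dag_depth + 1):
        nodes = [f"SYNPATH-L{lvl}N{i:02d}" for i in range(per_level)]
        for node in nodes:
            parents = {levels[lvl - 1][rng.integers(0, len(levels[lvl - 1]))]}
            if len(levels[lvl - 1]) > 1 and rng.random() < 0.3:
                parents.add(levels[lvl - 1][rng.integers(0, len(levels[lvl - 1]))])
            for p in sorted(parents):
                pe_rows.append({"parent": p, "child": node})
        levels.append(nodes)
    pathway_edges = pd.DataFrame(pe_rows, columns=["parent", "child"])

    all_terms = [n for lvl in levels[1:] for n in lvl]
    ann_rows = []
    for gid in genes:
        k = int(rng.integers(1, 4))
        for t in sorted(rng.choice(all_terms, size=k, replace=False)):
            ann_rows.append({"gene_id": gid, "pathway_id": t})
    annotations = pd.DataFrame(ann_rows, columns=["gene_id", "pathway_id"])

    clin_rows = []
    for bc in barcodes:
        clin_rows.append(
            {
                "barcode": bc,
                "project": _PROJECTS[rng.integers(0, len(_PROJECTS))],
                "stage": _DIRTY_STAGES[rng.integers(0, len(_DIRTY_STAGES))],
                "topography": _TOPOGRAPHY[rng.integers(0, len(_TOPOGRAPHY))],
            }
        )
    clinical = pd.DataFrame(clin_rows, columns=["barcode", "project", "stage", "topography"])
    return edges, pathway_edges, annotations, clinical, truth


# ---------------------------------------------------------------------------
# Full cohort bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    models: SyntheticModels
    calls: "pd.DataFrame"
    domains: "pd.DataFrame"
    counts: "pd.DataFrame"
    interactions: list
    pathway_edges: "pd.DataFrame"
    annotations: "pd.DataFrame"
    clinical: "pd.DataFrame"
    truth: GroundTruth


def generate_all(
    spec: SyntheticCohortSpec,
    n_planted_pairs: int = 2,
    n_planted_genes: int = 15,
    planted_lfc: float = 2.0,
) -> SyntheticCohort:
    """Generate the complete input bundle for one synthetic cohort.

    If the spec does not name planted pairs, effects are planted for up to
    ``n_planted_pairs`` of the most recurrent fusion pairs that qualify for
    the differential-expression stage — PK/TF category, in-frame, both
    partners contributing >30 aa, and a PK-/TF-pool domain intact in the
    fused protein (checked by direct substring arithmetic on the generator's
    own sequences). Samples carrying such a fusion become that pair's case
    group; the sign of ``planted_lfc`` alternates across pairs.
    """
    from dataclasses import replace as _replace

    from .fusion_annotation import canonical_pair, classify_category

    models = generate_gene_models(spec)
    calls, truth = generate_fusion_cohort(models, spec)
    domains, dom_classes = generate_domain_table(models, spec)
    truth.domain_class = dom_classes

    by_gene = models.by_gene()
    sym = {g: by_gene[g].symbol for g in by_gene}
    pair_name = (
        calls.apply(lambda r: "-".join(canonical_pair(sym[r.gene5], sym[r.gene3])), axis=1)
        if len(calls)
        else None
    )

    specific_accs = {a for a, c in dom_classes.items() if c != "neither"}
    dom_seqs: dict[str, list[str]] = {}
    for r in domains.itertuples(index=False):
        if r.accession in specific_accs:
            prot = models.proteins[r.protein]
            dom_seqs.setdefault(r.protein, []).append(prot[r.start - 1 : r.end])

    spec_eff = spec
    if not spec.planted_pairs and len(calls) and n_planted_pairs > 0:
        rng = np.random.default_rng([spec.seed, 6])
        eligible_idx = [
            i
            for i, r in calls.iterrows()
            if truth.frame_effect[i] == "in-frame"
            and truth.aa5[i] > 30
            and truth.aa3[i] > 30
            and classify_category(r.gene5, r.gene3, models.pk_genes, models.tf_genes) != "other"
            and any(
                seq in truth.protein[i]
                for g in (r.gene5, r.gene3)
                for seq in dom_seqs.get(g, ())
            )
        ]
        nsamp = (
            calls.loc[eligible_idx]
            .groupby(pair_name.loc[eligible_idx])["sample_barcode"]
            .nunique()
        )
        # prefer pairs with >=3 eligible samples (a 2v2 comparison has next
        # to no power); fall back to the >=2 grouping minimum
        strong = nsamp[nsamp >= 3]
        nsamp = strong if len(strong) else nsamp[nsamp >= 2]
        # greedy pick of the most recurrent pairs with disjoint sample sets,
        # so each case group carries exactly one planted effect
        chosen: list[str] = []
        taken: set[str] = set()
        for pair in nsamp.sort_values(ascending=False, kind="mergesort").index:
            pair_samples = set(calls.loc[pair_name == pair, "sample_barcode"])
            if pair_samples & taken:
                continue
            chosen.append(pair)
            taken |= pair_samples
            if len(chosen) == n_planted_pairs:
                break
        genes_all = sorted(by_gene)
        # a planted minority: median-of-ratios normalization assumes most
        # genes are unchanged, so never shift more than ~20% of the universe
        n_plant = min(n_planted_genes, max(1, len(genes_all) // 5))
        planted = []
        for k, pair in enumerate(chosen):
            pg = sorted(rng.choice(genes_all, size=n_plant, replace=False))
            lfc = planted_lfc if k % 2 == 0 else -planted_lfc
            planted.append((pair, tuple(pg), lfc))
        spec_eff = _replace(spec, planted_pairs=tuple(planted))

    # counts matrix covers every cohort sample, fusion-free ones included;
    # each sample maps to at most one planted pair
    rng_bc = np.random.default_rng([spec.seed, 2])
    all_barcodes = _barcodes(rng_bc, spec.n_samples)
    pair_of_sample: dict[str, str | None] = {bc: None for bc in all_barcodes}
    for pname, _, _ in spec_eff.planted_pairs:
        for bc in sorted(set(calls.loc[pair_name == pname, "sample_barcode"])):
            if pair_of_sample.get(bc) is None:
                pair_of_sample[bc] = pname

    counts, counts_truth = generate_counts(spec_eff, pair_of_sample, genes=sorted(by_gene))
    truth.planted_lfc = counts_truth.planted_lfc
    truth.case_samples = counts_truth.case_samples

    interactions, pw_edges, annotations, clinical, net_truth = generate_network_and_pathways(
        models, all_barcodes, spec
    )
    truth.nonphysical_edges = net_truth.nonphysical_edges

    return SyntheticCohort(
        spec=spec_eff,
        models=models,
        calls=calls,
        domains=domains,
        counts=counts,
        interactions=interactions,
        pathway_edges=pw_edges,
        annotations=annotations,
        clinical=clinical,
        truth=truth,
    )
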