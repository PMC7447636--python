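"""Readers and writers for every external format the pipeline touches.

All coordinates are 1-based inclusive (GTF convention). Parsing is strict:
violations raise :class:`ValidationError` / :class:`ParseError` rather than
being silently repaired, and every documented drop rule (self-loop edges,
``__``-prefixed HTSeq summary lines) is logged with a count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed data violates a documented invariant."""


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """One transcript of one gene.

    ``exons`` and ``cds`` are stored in genomic (ascending) order as 1-based
    inclusive intervals; transcript-orientation views are provided as
    properties. The CDS here includes the stop codon, so its total length is
    divisible by 3 and the encoded protein is ``cds_length/3 - 1`` residues.
    """

    gene_id: str
    symbol: str
    biotype: str
    contig: str
    strand: str
    transcript_id: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            prev_end = 0
            for s, e in ivs:
                if not (0 < s <= e):
                    raise ValidationError(f"{self.transcript_id}: bad {name} interval ({s},{e})")
                if s <= prev_end:
                    raise ValidationError(
                        f"{self.transcript_id}: {name} overlap or not sorted at ({s},{e})"
                    )
                prev_end = e
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        # CDS must be contained in the exon union
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS interval ({s},{e}) not inside one exon"
                )
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    # -- lengths ------------------------------------------------------------

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    # -- transcript-orientation views ---------------------------------------

    @property
    def exons_tx(self) -> tuple[Interval, ...]:
        """Exons ordered 5'->3' in transcript orientation."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def cds_tx(self) -> tuple[Interval, ...]:
        return self.cds if self.strand == "+" else tuple(reversed(self.cds))

    def genomic_to_tx(self, pos: int) -> int:
        """Map a genomic position inside an exon to a 0-based transcript offset."""
        off = 0
        for s, e in self.exons_tx:
            if s <= pos <= e:
                return off + (pos - s if self.strand == "+" else e - pos)
            off += e - s + 1
        raise ValidationError(f"{self.transcript_id}: position {pos} not exonic")

    @property
    def cds_tx_start(self) -> int:
        """0-based transcript offset of the first CDS base (the start codon A)."""
        first = self.cds_tx[0]
        return self.genomic_to_tx(first[0] if self.strand == "+" else first[1])

    @property
    def cds_tx_end(self) -> int:
        """0-based transcript offset one past the last CDS base."""
        return self.cds_tx_start + self.cds_length

    def donor_boundaries(self) -> list[tuple[int, int]]:
        """(transcript offset just past an exon end, genomic position of that end).

        Transcript-orientation 3' edges of every exon — the positions where a
        5' fusion partner can be cut (the last entry is the transcript end).
        """
        out = []
        off = 0
        for s, e in self.exons_tx:
            off += e - s + 1
            out.append((off, e if self.strand == "+" else s))
        return out

    def acceptor_boundaries(self) -> list[tuple[int, int]]:
        """(transcript offset of an exon start, genomic position of that start).

        Transcript-orientation 5' edges of every exon — the positions where a
        3' fusion partner can begin (the first entry is the transcript start).
        """
        out = []
        off = 0
        for s, e in self.exons_tx:
            out.append((off, s if self.strand == "+" else e))
            off += e - s + 1
        return out

    def transcript_sequence(self, contigs: dict[str, str]) -> str:
        seq = "".join(contigs[self.contig][s - 1 : e] for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_sequence(self, contigs: dict[str, str]) -> str:
        tx = self.transcript_sequence(contigs)
        return tx[self.cds_tx_start : self.cds_tx_end]

    def protein_sequence(self, contigs: dict[str, str]) -> str:
        cds = self.cds_sequence(contigs)
        return str(Seq(cds).translate(to_stop=True))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_COLS = 9


def write_gtf(models: list[GeneModel], path: str | Path) -> None:
    path = Path(path)
    lines = []
    for m in sorted(models, key=lambda m: (m.contig, m.gene_id, m.transcript_id)):
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'gene_name "{m.symbol}"; gene_biotype "{m.biotype}";'
        )
        span = (m.exons[0][0], m.exons[-1][1])
        for feat, ivs in (("gene", [span]), ("transcript", [span]), ("exon", m.exons), ("CDS", m.cds)):
            for s, e in ivs:
                lines.append(
                    "\t".join(
                        [m.contig, "fusionscope", feat, str(s), str(e), ".", m.strand, ".", attrs]
                    )
                )
    path.write_text("\n".join(lines) + "\n")


_ATTR_RE = re.compile(r'(\w+) "([^"]*)";?')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse a GTF file into validated :class:`GeneModel` objects.

    One model per transcript. Malformed lines raise :class:`ParseError` naming
    the line; models violating gene-model invariants raise
    :class:`ValidationError`.
    """
    import gffutils

    path = Path(path)
    # pre-scan for malformed rows so errors carry line numbers
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != _GTF_COLS:
            raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
        if not _ATTR_RE.search(fields[8]):
            raise ParseError(f"{path}:{lineno}: malformed attribute column")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[GeneModel] = []
    for t in db.features_of_type("transcript"):
        exons = tuple(sorted((f.start, f.end) for f in db.children(t, featuretype="exon")))
        cds = tuple(sorted((f.start, f.end) for f in db.children(t, featuretype="CDS")))
        models.append(
            GeneModel(
                gene_id=t.attributes["gene_id"][0],
                symbol=t.attributes.get("gene_name", [t.attributes["gene_id"][0]])[0],
                biotype=t.attributes.get("gene_biotype", ["protein_coding"])[0],
                contig=t.seqid,
                strand=t.strand,
                transcript_id=t.attributes["transcript_id"][0],
                exons=exons,
                cds=cds,
            )
        )
    return sorted(models, key=lambda m: (m.gene_id, m.transcript_id))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Interactions (PSI-MITAB subset)
# ---------------------------------------------------------------------------

#: interaction-type vocabulary accepted as physical binding evidence
PHYSICAL_TYPES = frozenset(
    {"physical association", "direct interaction", "association"}
)
#: detection-method vocabulary rejected as non-experimental
NONEXPERIMENTAL_METHODS = frozenset(
    {"in silico prediction", "inference", "predicted", "unknown", "text mining"}
)


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected interaction, canonicalized so ``protein_a <= protein_b``."""

    protein_a: str
    protein_b: str
    interaction_type: str
    detection_method: str
    is_physical: bool
    is_experimental: bool

    @property
    def is_supported(self) -> bool:
        return self.is_physical and self.is_experimental


def _edge_from_fields(a: str, b: str, itype: str, method: str) -> InteractionEdge:
    a, b = sorted((a, b))
    return InteractionEdge(
        protein_a=a,
        protein_b=b,
        interaction_type=itype,
        detection_method=method,
        is_physical=itype.lower() in PHYSICAL_TYPES,
        is_experimental=method.lower() not in NONEXPERIMENTAL_METHODS,
    )


MITAB_COLUMNS = [
    "protein_a",
    "protein_b",
    "detection_method",
    "interaction_type",
    "publication",
    "source",
]


def read_interactions(path: str | Path) -> list[InteractionEdge]:
    """Read a PSI-MITAB-style TSV.

    The native dialect is the 6-column subset in :data:`MITAB_COLUMNS`;
    full 15-column MITAB is accepted (columns 1, 2, 7, 12), extra columns
    ignored. Duplicated pairs collapse to one edge keeping the
    best-supported record; self-loops are dropped with a logged count.
    """
    path = Path(path)
    best: dict[tuple[str, str], InteractionEdge] = {}
    n_self = 0
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) >= 15:
            a, b, method, itype = f[0], f[1], f[6], f[11]
        elif len(f) >= 4:
            a, b, method, itype = f[0], f[1], f[2], f[3]
        else:
            raise ParseError(
                f"{path}:{lineno}: need >=4 columns (id_a, id_b, method, type), got {len(f)}"
            )
        if a == b:
            n_self += 1
            continue
        edge = _edge_from_fields(a, b, itype, method)
        key = (edge.protein_a, edge.protein_b)
        old = best.get(key)

        def _rank(e: InteractionEdge) -> tuple[int, int]:
            return (int(e.is_supported), int(e.is_physical) + int(e.is_experimental))

        if old is None or _rank(edge) > _rank(old):
            best[key] = edge
    if n_self:
        logger.warning("read_interactions: dropped %d self-loop edge(s)", n_self)
    return [best[k] for k in sorted(best)]


def write_interactions(edges: list[InteractionEdge], path: str | Path) -> None:
    lines = ["#" + "\t".join(MITAB_COLUMNS)]
    for e in sorted(edges, key=lambda e: (e.protein_a, e.protein_b)):
        lines.append(
            "\t".join(
                [e.protein_a, e.protein_b, e.detection_method, e.interaction_type, "-", "synthetic"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# HTSeq-count files
# ---------------------------------------------------------------------------

HTSEQ_SUMMARY_ROWS = [
    "__no_feature",
    "__ambiguous",
    "__too_low_aQual",
    "__not_aligned",
    "__alignment_not_unique",
]


def read_htseq_counts(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Read per-sample two-column HTSeq-count files into a genes x samples matrix.

    ``paths`` maps sample barcode -> file. ``__``-prefixed summary rows are
    excluded (logged). Inconsistent gene sets across files raise
    :class:`ValidationError` listing the symmetric difference; negative counts
    raise :class:`ValidationError`.
    """
    columns: dict[str, pd.Series] = {}
    gene_ref: list[str] | None = None
    n_summary = 0
    for barcode, p in paths.items():
        df = pd.read_csv(p, sep="\t", header=None, names=["gene", "count"], dtype={"gene": str})
        is_summary = df["gene"].str.startswith("__")
        n_summary += int(is_summary.sum())
        df = df[~is_summary]
        if (df["count"] < 0).any():
            bad = df.loc[df["count"] < 0, "gene"].iloc[0]
            raise ValidationError(f"{p}: negative count for gene {bad}")
        genes = df["gene"].tolist()
        if gene_ref is None:
            gene_ref = genes
        elif set(genes) != set(gene_ref):
            diff = sorted(set(genes) ^ set(gene_ref))
            raise ValidationError(f"inconsistent gene sets across count files: {diff}")
        columns[barcode] = pd.Series(df["count"].to_numpy(), index=genes)
    if n_summary:
        logger.info("read_htseq_counts: excluded %d '__' summary line(s)", n_summary)
    mat = pd.DataFrame(columns)
    mat.index.name = "gene_id"
    return mat


def write_htseq_counts(counts: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write one HTSeq-style file per sample column, with trailing summary rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for barcode in counts.columns:
        p = outdir / f"{barcode}.htseq.counts.tsv"
        with open(p, "w") as fh:
            for gene, v in counts[barcode].items():
                fh.write(f"{gene}\t{int(v)}\n")
            for row in HTSEQ_SUMMARY_ROWS:
                fh.write(f"{row}\t0\n")
        paths[barcode] = p
    return paths


# ---------------------------------------------------------------------------
# Plain TSV tables
# ---------------------------------------------------------------------------

FUSION_CALL_COLUMNS = [
    "sample_barcode",
    "gene5",
    "gene3",
    "contig5",
    "pos5",
    "contig3",
    "pos3",
]

DOMAIN_COLUMNS = ["protein", "accession", "name", "start", "end"]

CLINICAL_COLUMNS = ["barcode", "project", "stage", "topography"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_fusion_calls(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, FUSION_CALL_COLUMNS)
    df["pos5"] = df["pos5"].astype(int)
    df["pos3"] = df["pos3"].astype(int)
    return df


def write_fusion_calls(df: pd.DataFrame, path: str | Path) -> None:
    df[FUSION_CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_domain_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, DOMAIN_COLUMNS)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_domain_table(df: pd.DataFrame, path: str | Path) -> None:
    df[DOMAIN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    """Single-column (or first-column) gene-id list; '#' comments allowed."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(line.split("\t")[0])
    return genes


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, CLINICAL_COLUMNS)


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pathway_edges(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["parent", "child"])


def write_pathway_edges(df: pd.DataFrame, path: str | Path) -> None:
    df[["parent", "child"]].to_csv(path, sep="\t", index=False)


def read_pathway_annotations(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["gene_id", "pathway_id"])


def write_pathway_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "pathway_id"]].to_csv(path, sep="\t", index=False)
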