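"""Fusion transcript assembly, reading-frame prediction, and deduplication.

A fusion joins the 5' portion of one transcript (through an exon boundary)
to the 3' portion of another (from an exon boundary to the transcript end).
Translation starts at the 5' partner's annotated start codon; the fusion is
in-frame when the 3' partner's codon phase at the junction matches its
annotated CDS phase, so the downstream wild-type peptide is reproduced.

Conventions (tested explicitly):

* one canonical transcript per gene — the one with the longest CDS;
* the junction-spanning codon is attributed to the 3' partner (aa3);
* "both genes contributed over 30 amino acids" is read strictly: a fusion is
  protein-producing iff it is in-frame and aa5 >= 31 and aa3 >= 31;
* out-of-frame fusions are translated to the first stop and retained as
  records, but are never protein-producing;
* a junction upstream of the 5' CDS start is a promoter swap (the intact 3'
  gene placed under the 5' gene's promoter): no fusion protein is predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

AA_MIN = 30  # both partners must contribute strictly more than this


class UnresolvableCallError(ValueError):
    """A breakpoint does not coincide with any annotated exon boundary."""


@dataclass(frozen=True)
class FusedTranscript:
    sequence: str
    junction: int  # 0-based offset in fused coordinates where the 3' portion begins
    acceptor_offset: int  # 0-based transcript offset in the 3' partner
    model5: GeneModel
    model3: GeneModel


@dataclass(frozen=True)
class FusionProtein:
    sequence: str
    aa5: int
    aa3: int
    effect: str  # in-frame | out-of-frame | promoter-swap
    protein_producing: bool
    category: str = "other"

    def __post_init__(self) -> None:
        assert self.aa5 + self.aa3 == len(self.sequence)
        assert "*" not in self.sequence


def select_canonical(models: list[GeneModel]) -> dict[str, GeneModel]:
    """One transcript per gene: longest CDS, ties broken by transcript id."""
    best: dict[str, GeneModel] = {}
    for m in sorted(models, key=lambda m: (m.gene_id, -m.cds_length, m.transcript_id)):
        best.setdefault(m.gene_id, m)
    return best


def assemble_fusion_transcript(
    call, models: dict[str, GeneModel], contigs: dict[str, str]
) -> FusedTranscript:
    """Concatenate the 5' partner's transcript through its breakpoint exon
    boundary with the 3' partner's transcript from its boundary onward.

    ``call`` needs attributes gene5/gene3/contig5/pos5/contig3/pos3.
    Raises :class:`UnresolvableCallError` when a breakpoint is not an
    annotated boundary of the canonical transcript.
    """
    m5, m3 = models[call.gene5], models[call.gene3]
    junction = None
    for off, gpos in m5.donor_boundaries():
        if gpos == call.pos5 and m5.contig == call.contig5:
            junction = off
            break
    if junction is None:
        raise UnresolvableCallError(
            f"{call.gene5}: breakpoint {call.contig5}:{call.pos5} is not a donor exon boundary"
        )
    acceptor = None
    for off, gpos in m3.acceptor_boundaries():
        if gpos == call.pos3 and m3.contig == call.contig3:
            acceptor = off
            break
    if acceptor is None:
        raise UnresolvableCallError(
            f"{call.gene3}: breakpoint {call.contig3}:{call.pos3} is not an acceptor exon boundary"
        )
    tx5 = m5.transcript_sequence(contigs)
    tx3 = m3.transcript_sequence(contigs)
    return FusedTranscript(
        sequence=tx5[:junction] + tx3[acceptor:],
        junction=junction,
        acceptor_offset=acceptor,
        model5=m5,
        model3=m3,
    )


def determine_frame_and_translate(fused: FusedTranscript) -> FusionProtein:
    """Predict the fusion protein and its frame effect.

    aa5 counts codons completed strictly 5' of the junction; the
    junction-spanning codon and everything after belong to aa3. Translation
    runs from the 5' start codon to the first stop, so a stop upstream of (or
    spanning) the junction leaves aa3 = 0.
    """
    m5, m3 = fused.model5, fused.model3
    cds5_start = m5.cds_tx_start
    if fused.junction <= cds5_start:
        return FusionProtein("", 0, 0, "promoter-swap", False)
    p5 = fused.junction - cds5_start
    off3 = fused.acceptor_offset - m3.cds_tx_start
    inframe = (p5 % 3) == (off3 % 3)

    coding = fused.sequence[cds5_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate(to_stop=True))
    aa5 = min(p5 // 3, len(protein))
    return FusionProtein(
        sequence=protein,
        aa5=aa5,
        aa3=len(protein) - aa5,
        effect="in-frame" if inframe else "out-of-frame",
        protein_producing=classify_protein_producing(
            inframe, aa5, len(protein) - aa5
        ),
    )


def classify_protein_producing(inframe: bool, aa5: int, aa3: int) -> bool:
    """Protein-producing: in-frame and each partner contributes >30 aa."""
    return bool(inframe and aa5 > AA_MIN and aa3 > AA_MIN)


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Alphabetical gene-pair order (e.g. ERG-TMPRSS2, not TMPRSS2-ERG).

    The 5'/3' orientation is kept separately on the fusion record.
    """
    return tuple(sorted((gene_a, gene_b)))


def classify_category(gene5: str, gene3: str, pk: set[str], tf: set[str]) -> str:
    """PK-TF when one partner is a kinase and the other a transcription
    factor; otherwise PK, then TF, by any-partner membership; else other.
    A gene on both lists counts for both memberships."""
    pk5, pk3 = gene5 in pk, gene3 in pk
    tf5, tf3 = gene5 in tf, gene3 in tf
    if (pk5 and tf3) or (pk3 and tf5):
        return "PK-TF"
    if pk5 or pk3:
        return "PK"
    if tf5 or tf3:
        return "TF"
    return "other"


FUSION_KEY_COLUMNS = [
    "gene5",
    "gene3",
    "biotype5",
    "biotype3",
    "contig5",
    "pos5",
    "contig3",
    "pos3",
    "effect",
    "protein",
]

ANNOTATED_COLUMNS = [
    "sample_barcode",
    "gene5",
    "gene3",
    "symbol5",
    "symbol3",
    "pair",
    "biotype5",
    "biotype3",
    "contig5",
    "pos5",
    "contig3",
    "pos3",
    "effect",
    "aa5",
    "aa3",
    "protein",
    "protein_producing",
    "category",
    "status",
]


def annotate_calls(
    calls: pd.DataFrame,
    models: list[GeneModel] | dict[str, GeneModel],
    contigs: dict[str, str],
    pk: set[str],
    tf: set[str],
) -> pd.DataFrame:
    """Annotate every breakpoint call: assembly, frame, protein, category.

    Same-gene calls and calls whose breakpoints are not exon boundaries are
    retained with a non-'ok' status and excluded from the protein set.
    """
    canon = select_canonical(models) if isinstance(models, list) else models
    rows = []
    n_bad = 0
    for call in calls.itertuples(index=False):
        rec = {
            "sample_barcode": call.sample_barcode,
            "gene5": call.gene5,
            "gene3": call.gene3,
            "contig5": call.contig5,
            "pos5": int(call.pos5),
            "contig3": call.contig3,
            "pos3": int(call.pos3),
        }
        if call.gene5 == call.gene3:
            rec.update(
                symbol5="", symbol3="", pair="", biotype5="", biotype3="", effect="",
                aa5=0, aa3=0, protein="", protein_producing=False, category="other",
                status="rejected-same-gene",
            )
            rows.append(rec)
            n_bad += 1
            continue
        m5, m3 = canon[call.gene5], canon[call.gene3]
        rec.update(
            symbol5=m5.symbol,
            symbol3=m3.symbol,
            pair="-".join(canonical_pair(m5.symbol, m3.symbol)),
            biotype5=m5.biotype,
            biotype3=m3.biotype,
            category=classify_category(call.gene5, call.gene3, pk, tf),
        )
        try:
            fused = assemble_fusion_transcript(call, canon, contigs)
        except UnresolvableCallError as err:
            rec.update(
                effect="", aa5=0, aa3=0, protein="", protein_producing=False,
                status="unresolved",
            )
            logger.warning("unresolvable call: %s", err)
            rows.append(rec)
            n_bad += 1
            continue
        fp = determine_frame_and_translate(fused)
        rec.update(
            effect=fp.effect,
            aa5=fp.aa5,
            aa3=fp.aa3,
            protein=fp.sequence,
            protein_producing=fp.protein_producing,
            status="ok" if fp.effect != "promoter-swap" else "promoter-swap",
        )
        rows.append(rec)
    if n_bad:
        logger.info("annotate_calls: %d call(s) rejected or unresolved", n_bad)
    return pd.DataFrame(rows, columns=ANNOTATED_COLUMNS)


def deduplicate(fusions: pd.DataFrame) -> pd.DataFrame:
    """One representative per fusion key (gene ids, biotypes, breakpoints,
    frame effect, protein sequence). Idempotent and order-independent."""
    out = fusions.sort_values(ANNOTATED_COLUMNS, kind="mergesort").drop_duplicates(
        subset=FUSION_KEY_COLUMNS, keep="first"
    )
    n = len(fusions) - len(out)
    if n:
        logger.info("deduplicate: removed %d duplicate call(s)", n)
    return out.reset_index(drop=True)


def deduplicate_for_domains(fusions: pd.DataFrame) -> pd.DataFrame:
    """Second-pass dedup on (gene pair, protein sequence) for domain-level work.

    The parent table's index labels are preserved so that domain calls made
    on the deduplicated rows can be joined back to the full fusion table.
    """
    return fusions.sort_values(ANNOTATED_COLUMNS, kind="mergesort").drop_duplicates(
        subset=["pair", "protein"], keep="first"
    ).sort_index()
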