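"""Domain intactness on fusion proteins and PK/TF domain specificity.

A wild-type domain instance is *intact* in a fusion protein when its full
amino-acid sequence occurs unmodified in the predicted fusion protein —
junction-spanning matches count, truncation by even one residue does not.
A domain accession is PK-specific when >=95% of its intact copies in the
analyzed fusion set sit on protein-kinase sides (TF analogous).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

SPECIFICITY_THRESHOLD = 0.95
MIN_DOMAIN_LENGTH = 5


@dataclass(frozen=True)
class DomainInstance:
    """A domain's location and sequence on a wild-type protein (1-based aa coords)."""

    accession: str
    name: str
    protein: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.accession}@{self.protein}: bad coordinates")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(f"{self.accession}@{self.protein}: sequence/coordinate mismatch")
        if len(self.sequence) < MIN_DOMAIN_LENGTH:
            raise ValueError(f"{self.accession}@{self.protein}: domain shorter than {MIN_DOMAIN_LENGTH} aa")


def instances_from_table(domains: pd.DataFrame, proteins: dict[str, str]) -> list[DomainInstance]:
    """Attach WT protein substrings to a (protein, accession, name, start, end) table."""
    out = []
    for r in domains.itertuples(index=False):
        wt = proteins.get(r.protein)
        if wt is None or r.end > len(wt):
            logger.warning(
                "domain %s on %s outside protein bounds; skipped", r.accession, r.protein
            )
            continue
        out.append(
            DomainInstance(
                accession=r.accession,
                name=r.name,
                protein=r.protein,
                start=int(r.start),
                end=int(r.end),
                sequence=wt[int(r.start) - 1 : int(r.end)],
            )
        )
    return out


@dataclass(frozen=True)
class DomainCall:
    fusion_index: int
    instance: DomainInstance
    intact: bool
    side: str  # "5'" or "3'"


def assess_intactness(protein: str, aa5: int, instance: DomainInstance) -> tuple[bool, str]:
    """Exact full-length occurrence of the WT domain sequence in the fusion protein.

    The side is assigned from the matched position relative to the 5' partner's
    aa contribution: matches starting within the first ``aa5`` residues are 5'.
    """
    idx = protein.find(instance.sequence)
    if idx < 0:
        return False, ""
    return True, "5'" if idx < aa5 else "3'"


def call_domains(fusions: pd.DataFrame, instances: list[DomainInstance]) -> pd.DataFrame:
    """Assess every WT domain instance of both partners against each fusion protein.

    ``fusions`` is an annotated fusion table (needs gene5, gene3, protein,
    aa5); rows without a predicted protein are skipped. Each WT instance
    counts once per fusion regardless of how many times its sequence matches.
    """
    by_protein: dict[str, list[DomainInstance]] = {}
    for inst in instances:
        by_protein.setdefault(inst.protein, []).append(inst)
    rows = []
    for idx, row in fusions.iterrows():
        if not row["protein"]:
            continue
        for gene, partner_side in ((row["gene5"], "5'"), (row["gene3"], "3'")):
            for inst in by_protein.get(gene, []):
                intact, side = assess_intactness(row["protein"], int(row["aa5"]), inst)
                rows.append(
                    {
                        "fusion_index": idx,
                        "pair": row.get("pair", ""),
                        "accession": inst.accession,
                        "name": inst.name,
                        "wt_protein": inst.protein,
                        "wt_start": inst.start,
                        "wt_end": inst.end,
                        "intact": intact,
                        "side": side,
                        "partner_side": partner_side,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "fusion_index", "pair", "accession", "name", "wt_protein",
            "wt_start", "wt_end", "intact", "side", "partner_side",
        ],
    )


def classify_specificity(
    calls: pd.DataFrame,
    pk: set[str],
    tf: set[str],
    threshold: float = SPECIFICITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-accession PK/TF specificity over intact copies in the fusion set.

    Each intact copy is attributed to PK/TF by the wild-type protein carrying
    it. class = PK-specific iff copies_pk/copies_total >= threshold (TF
    analogous); accessions with zero intact copies are omitted.
    """
    intact = calls[calls["intact"]]
    rows = []
    for acc, grp in intact.groupby("accession"):
        total = len(grp)
        n_pk = int(grp["wt_protein"].isin(pk).sum())
        n_tf = int(grp["wt_protein"].isin(tf).sum())
        if n_pk / total >= threshold:
            cls = "PK-specific"
        elif n_tf / total >= threshold:
            cls = "TF-specific"
        else:
            cls = "neither"
        rows.append(
            {
                "accession": acc,
                "copies_total": total,
                "copies_pk": n_pk,
                "copies_tf": n_tf,
                "class": cls,
            }
        )
    return pd.DataFrame(
        rows, columns=["accession", "copies_total", "copies_pk", "copies_tf", "class"]
    ).sort_values("accession").reset_index(drop=True)


def summarize_domains(
    calls: pd.DataFrame,
    fusions: pd.DataFrame,
    specificity: pd.DataFrame | None = None,
) -> dict:
    """Mean intact domains per protein-producing fusion, overall and split
    PK/TF vs other, plus per-project PK-/TF-specific domain percentages."""
    pp = fusions[fusions["protein_producing"]]
    intact = calls[calls["intact"]]
    intact_pp = intact[intact["fusion_index"].isin(pp.index)]

    def _mean(sub: pd.DataFrame) -> float:
        return len(intact_pp[intact_pp["fusion_index"].isin(sub.index)]) / len(sub) if len(sub) else 0.0

    pktf = pp[pp["category"].isin(("PK", "TF", "PK-TF"))]
    other = pp[~pp["category"].isin(("PK", "TF", "PK-TF"))]
    out = {
        "n_intact_domains": int(len(intact_pp)),
        "mean_domains_per_fusion": _mean(pp),
        "mean_domains_pk_tf": _mean(pktf),
        "mean_domains_other": _mean(other),
    }
    if specificity is not None and "project" in fusions.columns:
        cls = specificity.set_index("accession")["class"]
        proj = fusions["project"]
        rows = []
        for project in sorted(proj.dropna().unique()):
            f_idx = fusions.index[proj == project]
            dom = intact_pp[intact_pp["fusion_index"].isin(f_idx)]
            total = len(dom)
            n_pk = int(dom["accession"].map(cls).eq("PK-specific").sum())
            n_tf = int(dom["accession"].map(cls).eq("TF-specific").sum())
            rows.append(
                {
                    "project": project,
                    "n_domains": total,
                    "pct_pk_specific": 100.0 * n_pk / total if total else 0.0,
                    "pct_tf_specific": 100.0 * n_tf / total if total else 0.0,
                }
            )
        out["per_project"] = pd.DataFrame(
            rows, columns=["project", "n_domains", "pct_pk_specific", "pct_tf_specific"]
        )
    return out
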