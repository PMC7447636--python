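"""Clinical joins, stage/topography harmonization, and breakpoint binning.

Fusion records are joined to clinical metadata on the TCGA barcode prefix
(first three dash-delimited fields). Stage strings are normalized
case-insensitively; sub-stage letters with optional numerals are stripped
("Stage IIA" -> "Stage II"), and non-stage entries ("Stage 0", "Stage X",
"I/II NOS") map to absent. ICD-O-3 topography codes are truncated at the
dot ("C56.9" -> "C56"). Breakpoints are placed into twenty 5%-of-contig
interval bins.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .io_formats import ValidationError

logger = logging.getLogger(__name__)

N_BINS = 20

_STAGE_IGNORE = {"stage 0", "stage x", "i/ii nos"}
_STAGE_RE = re.compile(r"stage\s+([ivx]+)(?:[abc]\d*)?", re.IGNORECASE)
_VALID_ROMAN = {"I", "II", "III", "IV"}
_TOPO_RE = re.compile(r"C\d+(\.\d+)?", re.IGNORECASE)


def barcode_key(barcode: str) -> str:
    """Joining key: the first three dash-delimited barcode fields."""
    return "-".join(str(barcode).split("-")[:3])


def simplify_stage(raw: object) -> str | None:
    """Map a raw stage string to one of Stage I..IV, or None.

    Idempotent: simplify_stage(simplify_stage(x)) == simplify_stage(x).
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    s = " ".join(str(raw).split()).lower()
    if not s or s in _STAGE_IGNORE:
        return None
    m = _STAGE_RE.fullmatch(s)
    if not m:
        return None
    roman = m.group(1).upper()
    return f"Stage {roman}" if roman in _VALID_ROMAN else None


def simplify_topography(code: object) -> str | None:
    """'C56.9' -> 'C56'; codes without a dot pass through; else None + warning."""
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return None
    s = str(code).strip()
    if not _TOPO_RE.fullmatch(s):
        if s:
            logger.warning("simplify_topography: non-conforming code %r", s)
        return None
    return s.split(".")[0].upper()


def bin_breakpoint(position: int, contig_length: int, n_bins: int = N_BINS) -> int:
    """floor(n_bins * (position-1) / contig_length), clamped to [0, n_bins-1]."""
    if not 1 <= position <= contig_length:
        raise ValidationError(
            f"position {position} outside [1, {contig_length}]"
        )
    return min(n_bins * (position - 1) // contig_length, n_bins - 1)


def bin_breakpoints(
    fusions: pd.DataFrame, contig_lengths: dict[str, int], n_bins: int = N_BINS
) -> pd.DataFrame:
    """Per-contig bin counts over both breakpoints of every fusion row."""
    counts: dict[tuple[str, int], int] = {}
    for row in fusions.itertuples(index=False):
        for contig, pos in ((row.contig5, row.pos5), (row.contig3, row.pos3)):
            b = bin_breakpoint(int(pos), contig_lengths[contig], n_bins)
            counts[(contig, b)] = counts.get((contig, b), 0) + 1
    rows = [
        {"contig": c, "bin_index": b, "count": n} for (c, b), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["contig", "bin_index", "count"])


def harmonize_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add simplified ``stage`` / ``topography`` columns (raw kept as *_raw)."""
    out = clinical.rename(columns={"stage": "stage_raw", "topography": "topography_raw"}).copy()
    out["stage"] = out["stage_raw"].map(simplify_stage)
    out["topography"] = out["topography_raw"].map(simplify_topography)
    return out


def join_clinical(fusions: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Left-join fusions to harmonized clinical records on the barcode prefix.

    Unmatched fusions are retained with absent clinical fields (counted in
    the log). A duplicated barcode key in the clinical table is an error.
    """
    clin = harmonize_clinical(clinical)
    clin["_key"] = clin["barcode"].map(barcode_key)
    dup = clin["_key"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate clinical barcode key(s): {sorted(clin.loc[dup, '_key'].unique())}"
        )
    fus = fusions.copy()
    fus["_key"] = fus["sample_barcode"].map(barcode_key)
    joined = fus.merge(
        clin[["_key", "project", "stage_raw", "stage", "topography_raw", "topography"]],
        on="_key",
        how="left",
    ).drop(columns="_key")
    n_unmatched = int(joined["project"].isna().sum())
    if n_unmatched:
        logger.info("join_clinical: %d fusion row(s) without clinical match", n_unmatched)
    return joined


PK_TF_CATEGORIES = ("PK", "TF", "PK-TF")


def summarize_by_project_stage(
    joined: pd.DataFrame, clinical: pd.DataFrame, min_samples: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(project, stage) PK/TF fusion burden and per-project PK/TF proportions.

    Counts are over unique fusion-sample pairs. Stage groups with fewer than
    ``min_samples`` samples are flagged rather than dropped. The per-project
    PK/TF proportion is the PK-or-TF fraction of protein-producing fusions,
    absent (NaN) when a project has none.
    """
    clin = harmonize_clinical(clinical)
    sample_counts = (
        clin.dropna(subset=["stage"])
        .groupby(["project", "stage"], as_index=False)["barcode"]
        .nunique()
        .rename(columns={"barcode": "n_samples"})
    )

    from .fusion_annotation import FUSION_KEY_COLUMNS

    uniq = joined.drop_duplicates(subset=FUSION_KEY_COLUMNS + ["sample_barcode"])
    pp = uniq[uniq["protein_producing"]]
    pk_tf = pp[pp["category"].isin(PK_TF_CATEGORIES)]
    fusion_counts = (
        pk_tf.dropna(subset=["stage"])
        .groupby(["project", "stage"], as_index=False)
        .size()
        .rename(columns={"size": "n_pk_tf_fusions"})
    )
    stage_df = sample_counts.merge(fusion_counts, on=["project", "stage"], how="left")
    stage_df["n_pk_tf_fusions"] = stage_df["n_pk_tf_fusions"].fillna(0).astype(int)
    stage_df["fusions_per_sample"] = stage_df["n_pk_tf_fusions"] / stage_df["n_samples"]
    stage_df["small_group"] = stage_df["n_samples"] < min_samples
    stage_df = stage_df.sort_values(["project", "stage"]).reset_index(drop=True)

    proj_rows = []
    for project, grp in pp.dropna(subset=["project"]).groupby("project"):
        n_pp = len(grp)
        n_pktf = int(grp["category"].isin(PK_TF_CATEGORIES).sum())
        proj_rows.append(
            {
                "project": project,
                "n_protein_producing": n_pp,
                "n_pk_tf": n_pktf,
                "pk_tf_proportion": n_pktf / n_pp if n_pp else np.nan,
            }
        )
    project_df = pd.DataFrame(
        proj_rows, columns=["project", "n_protein_producing", "n_pk_tf", "pk_tf_proportion"]
    ).sort_values("project").reset_index(drop=True)
    return stage_df, project_df
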