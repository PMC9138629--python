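"""Join miRNA regulation, degradome-validated cleavage and target
expression into classified regulatory pairs and the final shortlist.

A pair is "contrasting" when the miRNA class and the target class oppose
each other in the direction cleavage predicts:

* miR up, target down      -> repression_by_induced_mir
* miR down, target up      -> derepression_by_reduced_mir
* miR unique_shade, target down -> shade_specific_silencing
* miR unique_sun, target up     -> absence_release
* miR neutral, target up/down   -> differential_binding_candidate

Every other combination is discordant and excluded from the shortlist.
All classes require degradome evidence (a cleavage hit of category 0-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .degradome import CleavageHit
from .expression import ExpressionRecord, RegulationCall

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryPair",
    "INTERACTION_CLASSES",
    "CONTRASTING_CLASSES",
    "classify_pair",
    "build_shortlist",
    "pathway_tally",
    "load_reference_shortlist",
    "SHORTLIST_COLUMNS",
]

INTERACTION_CLASSES = (
    "repression_by_induced_mir",
    "derepression_by_reduced_mir",
    "shade_specific_silencing",
    "absence_release",
    "differential_binding_candidate",
    "discordant",
)
CONTRASTING_CLASSES = frozenset(INTERACTION_CLASSES[:-1])

SHORTLIST_COLUMNS = [
    "mirna",
    "target_id",
    "gene_name",
    "function",
    "t_start",
    "t_stop",
    "cleavage_site",
    "category",
    "allen_score",
    "p_value",
    "mfe_perfect",
    "mfe_site",
    "sequence",
    "structure",
    "mir_regulation",
]


@dataclass
class RegulatoryPair:
    mir_call: RegulationCall
    hit: CleavageHit
    target_expr: ExpressionRecord
    interaction_class: str

    @property
    def contrasting(self) -> bool:
        return self.interaction_class in CONTRASTING_CLASSES


def classify_pair(
    mir_call: RegulationCall,
    target_expr: ExpressionRecord,
    hit: CleavageHit,
) -> RegulatoryPair:
    """Classify one miR-target pair; pure function of the three records."""
    if hit is None or hit.category is None or not 0 <= hit.category <= 4:
        raise ValueError("pair rejected: no degradome cleavage evidence (category 0-4)")
    if hit.transcript_id != target_expr.transcript_id:
        raise ValueError(
            f"pair rejected: cleavage hit on {hit.transcript_id!r} but "
            f"expression record for {target_expr.transcript_id!r}"
        )
    m, t = mir_call.reg_class, target_expr.expr_class
    if m == "up" and t == "down":
        cls = "repression_by_induced_mir"
    elif m == "down" and t == "up":
        cls = "derepression_by_reduced_mir"
    elif m == "unique_shade" and t == "down":
        cls = "shade_specific_silencing"
    elif m == "unique_sun" and t == "up":
        cls = "absence_release"
    elif m == "neutral" and t != "neutral":
        cls = "differential_binding_candidate"
    else:
        cls = "discordant"
    return RegulatoryPair(mir_call, hit, target_expr, cls)


def build_shortlist(
    pairs: Sequence[RegulatoryPair],
    annotation: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Shortlist table of contrasting pairs, one row per pair.

    ``annotation`` maps target id -> (gene name, function); missing entries
    leave those fields empty (logged).  Rows are ordered by miRNA id then
    target id; the regulation class is an explicit column.
    """
    annotation = annotation or {}
    rows = []
    for p in pairs:
        if not p.contrasting:
            continue
        tid = p.target_expr.transcript_id
        gene, func = annotation.get(tid, ("", ""))
        if tid not in annotation and annotation:
            logger.warning("no annotation for target %s", tid)
        a = p.hit.alignment
        rows.append(
            {
                "mirna": p.mir_call.feature_id,
                "target_id": tid,
                "gene_name": gene,
                "function": func,
                "t_start": a.t_start,
                "t_stop": a.t_stop,
                "cleavage_site": a.expected_cs,
                "category": p.hit.category,
                "allen_score": a.allen_score,
                "p_value": p.hit.p_value,
                "mfe_perfect": a.mfe_perfect,
                "mfe_site": a.mfe_site,
                "sequence": a.sequence,
                "structure": a.structure,
                "mir_regulation": p.mir_call.reg_class,
            }
        )
    df = pd.DataFrame(rows, columns=SHORTLIST_COLUMNS)
    if not df.empty:
        df = df.sort_values(["mirna", "target_id"], kind="stable").reset_index(drop=True)
    return df


def pairs_to_frame(pairs: Sequence[RegulatoryPair]) -> pd.DataFrame:
    """Full pair table, discordant pairs included."""
    rows = [
        {
            "mirna": p.mir_call.feature_id,
            "target_id": p.target_expr.transcript_id,
            "mir_log2fc": p.mir_call.log2fc,
            "mir_class": p.mir_call.reg_class,
            "target_log2fc": p.target_expr.log2fc,
            "target_class": p.target_expr.expr_class,
            "cleavage_site": p.hit.alignment.expected_cs,
            "category": p.hit.category,
            "p_value": p.hit.p_value,
            "interaction_class": p.interaction_class,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "target_id", "mir_log2fc", "mir_class", "target_log2fc",
            "target_class", "cleavage_site", "category", "p_value",
            "interaction_class",
        ],
    )


def pathway_tally(
    pairs: Sequence[RegulatoryPair],
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """Percentage distribution of target pathway labels, overall and split
    by miRNA regulation direction.  Unmapped targets count as "unknown".
    Percentages sum to 100 within each split."""
    rows = []
    for p in pairs:
        tid = p.target_expr.transcript_id
        rows.append(
            {
                "pathway": category_map.get(tid, "unknown"),
                "mir_regulation": p.mir_call.reg_class,
            }
        )
    df = pd.DataFrame(rows, columns=["pathway", "mir_regulation"])
    out = []
    splits = [("overall", df)] + [
        (reg, sub) for reg, sub in df.groupby("mir_regulation")
    ]
    for name, sub in splits:
        if sub.empty:
            continue
        pct = sub["pathway"].value_counts(normalize=True) * 100.0
        for pathway, value in pct.sort_index().items():
            out.append({"split": name, "pathway": pathway, "percent": value})
    return pd.DataFrame(out, columns=["split", "pathway", "percent"])


def load_reference_shortlist() -> pd.DataFrame:
    """The packaged reference shortlist of 16 miRNAs / 21 target pairs
    (transcribed printed values; display provenance, not recomputed)."""
    with resources.files("shademir.data").joinpath("table1_shortlist.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False, dtype={"unique_condition": str})
    for col in ("t_start", "t_stop", "cleavage_site", "category"):
        df[col] = df[col].astype(int)
    for col in ("allen_score", "p_value", "mfe_perfect", "mfe_site"):
        df[col] = df[col].astype(float)
    return df
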