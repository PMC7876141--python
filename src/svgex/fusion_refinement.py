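"""Refinement of RNA-seq fusion candidates with WGS SSV support.

Candidates are first filtered against a banned-pair list and same-gene
events.  Surviving calls are annotated with gene-body SSV support
(breakend within the annotated span of one or both partners in the same
tumor) and a high-expression flag, and tiered:

* ``ssv_supported_high_expr`` -- SSV support and high expression,
* ``ssv_supported`` -- SSV support only,
* ``rna_only`` -- neither.

High expression holds when either (1) the fusion occurs in at most two
tumors and in each such tumor either partner scores > 0.4 SD from its
cohort median, or (2) either partner has a breakpoint-expression
association with p < 0.01 and positive direction by the gene-body
window or the distance metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import GeneAnnotation, SSVRecord

logger = logging.getLogger(__name__)

SD_THRESHOLD = 0.4
ASSOC_P_THRESHOLD = 0.01

TIERS = ("ssv_supported_high_expr", "ssv_supported", "rna_only")


@dataclass(frozen=True)
class FusionCandidate:
    gene_a: str
    gene_b: str
    tumor_id: str
    caller: str
    banned: bool = False

    @property
    def same_gene(self) -> bool:
        return self.gene_a == self.gene_b

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True)
class RefinedFusion:
    candidate: FusionCandidate
    ssv_support: str  # none | one_gene | both_genes
    high_expression: bool
    tier: str


def candidates_from_frame(df: pd.DataFrame) -> list[FusionCandidate]:
    return [
        FusionCandidate(str(r.gene_a), str(r.gene_b), str(r.tumor_id), str(r.caller))
        for r in df.itertuples(index=False)
    ]


def filter_candidates(
    calls: Sequence[FusionCandidate], banned_pairs: set[frozenset[str]]
) -> tuple[list[FusionCandidate], dict[str, int]]:
    """Drop banned-pair (either order) and same-gene candidates."""
    kept: list[FusionCandidate] = []
    n_banned = n_same = 0
    for c in calls:
        if c.same_gene:
            n_same += 1
        elif c.pair in banned_pairs:
            n_banned += 1
        else:
            kept.append(c)
    stats = {"input": len(calls), "removed_banned": n_banned,
             "removed_same_gene": n_same, "kept": len(kept)}
    logger.info("fusion filtering: %s", stats)
    return kept, stats


def annotate_ssv_support(
    call: FusionCandidate,
    ssvs: Sequence[SSVRecord],
    genes: Sequence[GeneAnnotation] | dict[str, GeneAnnotation],
) -> str:
    gene_map = genes if isinstance(genes, dict) else {g.gene_id: g for g in genes}
    hits = set()
    for name in (call.gene_a, call.gene_b):
        g = gene_map.get(name)
        if g is None:
            logger.warning("fusion partner %s missing from annotation", name)
            continue
        for s in ssvs:
            if s.tumor_id != call.tumor_id:
                continue
            for chrom, pos, _ in s.breakends:
                if chrom == g.chrom and g.start <= pos < g.end:
                    hits.add(name)
                    break
    if not hits:
        return "none"
    if call.gene_a in hits and call.gene_b in hits:
        return "both_genes"
    return "one_gene"


def annotate_high_expression(
    call: FusionCandidate,
    sd_scores: pd.DataFrame,
    assoc_body: pd.DataFrame | None,
    assoc_dist: pd.DataFrame | None,
    recurrence: int,
) -> bool:
    if recurrence <= 2:
        for name in (call.gene_a, call.gene_b):
            if name in sd_scores.index and call.tumor_id in sd_scores.columns:
                score = sd_scores.loc[name, call.tumor_id]
                if pd.notna(score) and score > SD_THRESHOLD:
                    return True
    for assoc in (assoc_body, assoc_dist):
        if assoc is None or assoc.empty:
            continue
        hit = assoc[
            assoc["gene_id"].isin((call.gene_a, call.gene_b))
            & (assoc["p_value"] < ASSOC_P_THRESHOLD)
            & (assoc["direction"] == "positive")
        ]
        if not hit.empty:
            return True
    return False


def refine_fusions(
    calls: Sequence[FusionCandidate],
    banned_pairs: set[frozenset[str]],
    ssvs: Sequence[SSVRecord],
    genes: Sequence[GeneAnnotation],
    sd_scores: pd.DataFrame,
    assoc_body: pd.DataFrame | None = None,
    assoc_dist: pd.DataFrame | None = None,
) -> tuple[list[RefinedFusion], dict[str, int]]:
    """Full refinement: filter, annotate support and expression, tier."""
    kept, stats = filter_candidates(calls, banned_pairs)
    gene_map = {g.gene_id: g for g in genes}
    by_tumor: dict[str, list[SSVRecord]] = {}
    for s in ssvs:
        by_tumor.setdefault(s.tumor_id, []).append(s)

    # recurrence: distinct tumors per unordered pair
    recurrence: dict[frozenset[str], set[str]] = {}
    for c in kept:
        recurrence.setdefault(c.pair, set()).add(c.tumor_id)

    refined: list[RefinedFusion] = []
    for c in kept:
        support = annotate_ssv_support(c, by_tumor.get(c.tumor_id, []), gene_map)
        high = annotate_high_expression(
            c, sd_scores, assoc_body, assoc_dist, len(recurrence[c.pair])
        )
        if support != "none" and high:
            tier = "ssv_supported_high_expr"
        elif support != "none":
            tier = "ssv_supported"
        else:
            tier = "rna_only"
        refined.append(RefinedFusion(c, support, high, tier))
    stats["tier1"] = sum(r.tier == "ssv_supported_high_expr" for r in refined)
    stats["tier2"] = sum(r.tier == "ssv_supported" for r in refined)
    return refined, stats


def refined_to_frame(refined: Sequence[RefinedFusion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [r.candidate.gene_a for r in refined],
            "gene_b": [r.candidate.gene_b for r in refined],
            "tumor_id": [r.candidate.tumor_id for r in refined],
            "caller": [r.candidate.caller for r in refined],
            "ssv_support": [r.ssv_support for r in refined],
            "high_expression": [r.high_expression for r in refined],
            "tier": [r.tier for r in refined],
        }
    )
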