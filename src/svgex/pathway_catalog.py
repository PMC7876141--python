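"""Per-gene and per-pathway somatic alteration tabulation.

For each (tumor, gene) at most one alteration is recorded, chosen by
the precedence order ``snv_indel > fusion > deep_deletion >
amplification > ssv_cis``.  SSV-based cis alterations are admitted only
for genes passing the FDR gate (significant by the gene-body or 1 Mb
association), with role-specific rules: oncogenes need a breakpoint
within 1 Mb of the TSS plus expression > +0.4 SD; tumor suppressors
need a gene-body breakpoint plus expression < -0.4 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .breakpoint_matrices import BreakpointPresenceMatrix
from .io_formats import TumorMeta

logger = logging.getLogger(__name__)

ALTERATION_PRECEDENCE = (
    "snv_indel",
    "fusion",
    "deep_deletion",
    "amplification",
    "ssv_cis",
)

INACTIVATING_CONSEQUENCES = {
    "nonsense", "nonstop", "frameshift_indel", "indel", "frame_shift_del",
    "frame_shift_ins", "splice_site",
}

SD_THRESHOLD = 0.4
FDR_GATE = 0.10


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    roles: dict[str, str]  # gene -> oncogene | tumor_suppressor
    enabled: bool = True

    def __post_init__(self) -> None:
        bad = {g: r for g, r in self.roles.items() if r not in ("oncogene", "tumor_suppressor")}
        if bad:
            raise ValueError(f"pathway {self.name}: invalid roles {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.roles)


@dataclass(frozen=True)
class AlterationCall:
    tumor_id: str
    gene_id: str
    alteration: str
    evidence: str = ""


def load_pathways(path: str | Path | None = None, include_disabled: bool = False) -> list[PathwayDefinition]:
    """Load pathway definitions from YAML (the shipped catalog by default)."""
    if path is None:
        text = resources.files("svgex.data").joinpath("pathways.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out = []
    for entry in raw["pathways"]:
        p = PathwayDefinition(
            name=entry["name"],
            roles=dict(entry["genes"]),
            enabled=entry.get("enabled", True),
        )
        if p.enabled or include_disabled:
            out.append(p)
    return out


def _qualifying_mutation(row, role: str) -> bool:
    inactivating = str(row.consequence).lower() in INACTIVATING_CONSEQUENCES
    if role == "oncogene":
        return bool(row.hotspot)
    return bool(row.hotspot) or inactivating


def call_alterations(
    tumors: Sequence[str],
    pathways: Sequence[PathwayDefinition],
    mutations: pd.DataFrame | None,
    fusions: pd.DataFrame | None,
    cna: pd.DataFrame | None,
    gated_genes: set[str],
    presence_body: BreakpointPresenceMatrix | None,
    presence_1mb: BreakpointPresenceMatrix | None,
    sd_scores: pd.DataFrame | None,
) -> pd.DataFrame:
    """Tabulate per-(tumor, gene) alterations over the pathway genes.

    ``gated_genes`` is the FDR < 10% set from the breakpoint-expression
    associations (gene-body or 1 Mb window); ``fusions`` is a refined
    fusion table already restricted to supported calls.
    """
    roles: dict[str, str] = {}
    for p in pathways:
        for g, r in p.roles.items():
            roles.setdefault(g, r)

    mut_idx: dict[tuple[str, str], list] = {}
    if mutations is not None:
        for row in mutations.itertuples(index=False):
            mut_idx.setdefault((str(row.tumor_id), str(row.gene)), []).append(row)

    fusion_pairs: set[tuple[str, str]] = set()
    if fusions is not None:
        for row in fusions.itertuples(index=False):
            fusion_pairs.add((str(row.tumor_id), str(row.gene_a)))
            fusion_pairs.add((str(row.tumor_id), str(row.gene_b)))

    tumor_set = list(tumors)
    rows: list[AlterationCall] = []
    missing_genes: set[str] = set()
    for gene, role in roles.items():
        known_anywhere = any(
            (tbl is not None and gene in getattr(tbl, "index", ()))
            for tbl in (cna, sd_scores)
        ) or any((t, gene) in mut_idx for t in tumor_set) or any(
            (t, gene) in fusion_pairs for t in tumor_set
        )
        if not known_anywhere:
            missing_genes.add(gene)
            continue
        for tumor in tumor_set:
            alteration = None
            evidence = ""
            hits = mut_idx.get((tumor, gene), [])
            if any(_qualifying_mutation(h, role) for h in hits):
                alteration, evidence = "snv_indel", "mutation table"
            elif (tumor, gene) in fusion_pairs:
                alteration, evidence = "fusion", "refined fusion"
            elif cna is not None and gene in cna.index and tumor in cna.columns and cna.loc[gene, tumor] == -2:
                alteration, evidence = "deep_deletion", "thresholded CNA -2"
            elif cna is not None and gene in cna.index and tumor in cna.columns and cna.loc[gene, tumor] == 2:
                alteration, evidence = "amplification", "thresholded CNA +2"
            elif gene in gated_genes and sd_scores is not None and gene in sd_scores.index and tumor in sd_scores.columns:
                score = sd_scores.loc[gene, tumor]
                if role == "oncogene":
                    pres = presence_1mb
                    ok = (
                        pres is not None
                        and gene in pres.values.index
                        and tumor in pres.values.columns
                        and pres.values.loc[gene, tumor] == 1
                        and pd.notna(score)
                        and score > SD_THRESHOLD
                    )
                else:
                    pres = presence_body
                    ok = (
                        pres is not None
                        and gene in pres.values.index
                        and tumor in pres.values.columns
                        and pres.values.loc[gene, tumor] == 1
                        and pd.notna(score)
                        and score < -SD_THRESHOLD
                    )
                if ok:
                    alteration, evidence = "ssv_cis", f"breakpoint + expression {score:+.2f} SD"
            if alteration is not None:
                rows.append(AlterationCall(tumor, gene, alteration, evidence))
    if missing_genes:
        logger.info("pathway genes absent from all inputs, skipped: %s", sorted(missing_genes))
    return pd.DataFrame(
        [(c.tumor_id, c.gene_id, c.alteration, c.evidence) for c in rows],
        columns=["tumor_id", "gene_id", "alteration", "evidence"],
    )


def pathway_matrix(
    alterations: pd.DataFrame,
    pathways: Sequence[PathwayDefinition],
    tumors: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Pathway x tumor altered/not matrix and per-pathway altered fraction."""
    altered_pairs = set(zip(alterations["tumor_id"], alterations["gene_id"]))
    mat = pd.DataFrame(False, index=[p.name for p in pathways], columns=list(tumors))
    for p in pathways:
        genes = set(p.genes)
        for tumor in tumors:
            if any((tumor, g) in altered_pairs for g in genes):
                mat.loc[p.name, tumor] = True
    fractions = mat.mean(axis=1).rename("altered_fraction")
    return mat, fractions


def pathway_type_enrichment(
    pmat: pd.DataFrame,
    meta: Sequence[TumorMeta],
    focus_types: Sequence[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of pathway alteration within each
    focus tumor type versus all other tumors."""
    by_id = {m.tumor_id: m.tumor_type for m in meta}
    observed = {by_id[t] for t in pmat.columns if t in by_id}
    rows = []
    tumors = [t for t in pmat.columns if t in by_id]
    n_total = len(tumors)
    for ftype in focus_types:
        in_type = [t for t in tumors if by_id[t] == ftype]
        if not in_type:
            continue
        for pathway in pmat.index:
            altered = pmat.loc[pathway, tumors]
            k_total = int(altered.sum())
            k_type = int(altered[in_type].sum())
            if k_total == 0:
                p = 1.0
            else:
                p = float(stats.hypergeom.sf(k_type - 1, n_total, k_total, len(in_type)))
            rows.append((pathway, ftype, k_type, len(in_type), k_total, p))
    return pd.DataFrame(
        rows,
        columns=["pathway", "tumor_type", "n_altered_in_type", "n_type", "n_altered_total", "p_value"],
    )
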