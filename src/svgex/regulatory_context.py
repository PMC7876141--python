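"""TAD-disruption and enhancer-translocation annotation of SSVs.

TAD classification: an SSV is ``preserving`` when both breakends fall
inside the same TAD interval, ``disrupting`` when both fall in TADs but
not the same one (different chromosomes included), and ``unresolved``
when either breakend lies outside all TAD annotation.

Enhancer translocation: for a breakend 0-500 kb upstream of a gene with
the fused side pointing away from the gene (orientation rule below),
the mate breakend's retained side is searched for the nearest enhancer
within 500 kb; a call is emitted only if the unaltered gene has no
enhancer within 1 Mb of its TSS, or only one farther than the
translocated enhancer.  Orientation rule: a positive-strand gene
requires ``negative`` orientation at the proximal breakend (downstream
sequence retained, so the gene side is kept); a negative-strand gene
requires ``positive`` orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .breakpoint_matrices import BreakpointPresenceMatrix
from .io_formats import GeneAnnotation, IntervalSet, SSVRecord

TAD_CLASSES = ("preserving", "disrupting", "unresolved")

DEFAULT_FUSED_WINDOW = 500_000
DEFAULT_NATIVE_WINDOW = 1_000_000
DEFAULT_PROXIMAL_WINDOW = 500_000


@dataclass(frozen=True)
class TADClass:
    ssv_id: str
    tad_class: str


@dataclass(frozen=True)
class EnhancerTranslocationCall:
    ssv_id: str
    gene_id: str
    tumor_id: str
    translocated_enhancer: tuple[str, int, int]
    distance_to_breakend: int
    native_enhancer_distance: int | None


class TADIndex:
    """Containment lookups over validated non-overlapping TADs."""

    def __init__(self, tads: IntervalSet):
        self._by_chrom: dict[str, np.ndarray] = {}
        for chrom, arr in tads.by_chrom().items():
            order = np.argsort(arr[:, 0])
            arr = arr[order]
            if len(arr) > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"TADs overlap on {chrom}")
            self._by_chrom[chrom] = arr

    def find(self, chrom: str, pos: int) -> int | None:
        """Index of the TAD containing pos on chrom, or None."""
        arr = self._by_chrom.get(chrom)
        if arr is None or len(arr) == 0:
            return None
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        if i >= 0 and arr[i, 0] <= pos < arr[i, 1]:
            return i
        return None


def classify_tad(ssv: SSVRecord, tads: IntervalSet | TADIndex) -> TADClass:
    index = tads if isinstance(tads, TADIndex) else TADIndex(tads)
    i1 = index.find(ssv.chrom1, ssv.pos1)
    i2 = index.find(ssv.chrom2, ssv.pos2)
    if i1 is None or i2 is None:
        cls = "unresolved"
    elif ssv.chrom1 != ssv.chrom2 or i1 != i2:
        cls = "disrupting"
    else:
        cls = "preserving"
    return TADClass(ssv_id=ssv.ssv_id, tad_class=cls)


def classify_tads(ssvs: Iterable[SSVRecord], tads: IntervalSet) -> list[TADClass]:
    index = TADIndex(tads)
    return [classify_tad(s, index) for s in ssvs]


def _two_by_two_chi2(table: np.ndarray) -> tuple[float, float, bool]:
    """Chi-squared p for a 2x2 table; Fisher fallback when expected < 5."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0 or np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return np.nan, 1.0, False
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.any(expected < 5):
        _, p = stats.fisher_exact(table.astype(int))
        return np.nan, float(p), True
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), False


def tad_enrichment(
    tad_classes: Sequence[TADClass], altered_ssv_ids: set[str]
) -> dict:
    """Chi-squared comparing the disrupting fraction among expression-
    altered SSVs against all classified SSVs (unresolved excluded)."""
    resolved = [c for c in tad_classes if c.tad_class != "unresolved"]
    ids = {c.ssv_id for c in resolved} | {
        c.ssv_id for c in tad_classes if c.tad_class == "unresolved"
    }
    unknown = altered_ssv_ids - {c.ssv_id for c in tad_classes}
    if unknown:
        raise ValueError(f"altered SSV ids not classified: {sorted(unknown)[:5]}")
    if not altered_ssv_ids:
        raise ValueError("altered SSV set is empty")
    alt = [c for c in resolved if c.ssv_id in altered_ssv_ids]
    a_dis = sum(c.tad_class == "disrupting" for c in alt)
    a_pre = len(alt) - a_dis
    t_dis = sum(c.tad_class == "disrupting" for c in resolved)
    t_pre = len(resolved) - t_dis
    table = np.asarray([[a_dis, a_pre], [t_dis, t_pre]])
    chi2, p, fisher = _two_by_two_chi2(table)
    if fisher:
        warnings.warn("tad_enrichment: expected cell < 5, Fisher exact used", stacklevel=2)
    return {
        "chi2": chi2,
        "p_value": p,
        "altered_disrupting": a_dis,
        "altered_total": len(alt),
        "all_disrupting": t_dis,
        "all_total": len(resolved),
        "fisher_fallback": fisher,
    }


def _enhancer_midpoints(enhancers: IntervalSet) -> dict[str, np.ndarray]:
    out = {}
    for chrom, arr in enhancers.by_chrom().items():
        mids = (arr[:, 0] + arr[:, 1]) // 2
        order = np.argsort(mids)
        out[chrom] = np.column_stack([mids[order], arr[order, 0], arr[order, 1]])
    return out


def _nearest(mids: np.ndarray, pos: int, lo: int, hi: int):
    """Nearest enhancer (by midpoint) to pos with midpoint in [lo, hi]."""
    if mids is None or len(mids) == 0:
        return None
    m = mids[:, 0]
    i0 = np.searchsorted(m, lo, side="left")
    i1 = np.searchsorted(m, hi, side="right")
    if i0 >= i1:
        return None
    cand = mids[i0:i1]
    j = int(np.argmin(np.abs(cand[:, 0] - pos)))
    return cand[j]


def _proximal_qualifies(gene: GeneAnnotation, chrom: str, pos: int, orient: str,
                        proximal_window: int) -> bool:
    if chrom != gene.chrom:
        return False
    tss = gene.tss
    if gene.strand == "+":
        return (tss - proximal_window <= pos < tss) and orient == "negative"
    return (tss < pos <= tss + proximal_window) and orient == "positive"


def detect_enhancer_translocation(
    ssv: SSVRecord,
    gene: GeneAnnotation,
    enhancers: IntervalSet | dict[str, np.ndarray],
    max_fused: int = DEFAULT_FUSED_WINDOW,
    native_window: int = DEFAULT_NATIVE_WINDOW,
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
) -> EnhancerTranslocationCall | None:
    """Evaluate one SSV against one gene for enhancer translocation."""
    if gene.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.gene_id} lacks a strand")
    mids = (
        enhancers if isinstance(enhancers, dict) else _enhancer_midpoints(enhancers)
    )
    tss = gene.tss
    ends = list(ssv.breakends)
    candidates = []
    for i, (chrom, pos, orient) in enumerate(ends):
        if _proximal_qualifies(gene, chrom, pos, orient, proximal_window):
            candidates.append((abs(pos - tss), i))
    if not candidates:
        return None
    _, i = min(candidates)
    mate_chrom, mate_pos, mate_orient = ends[1 - i]

    # fused side of the mate: the retained direction given by its orientation
    if mate_orient == "positive":
        lo, hi = mate_pos - max_fused, mate_pos
    else:
        lo, hi = mate_pos, mate_pos + max_fused
    fused = _nearest(mids.get(mate_chrom), mate_pos, lo, hi)
    if fused is None:
        return None
    dist_fused = int(abs(int(fused[0]) - mate_pos))

    native = _nearest(
        mids.get(gene.chrom), tss, tss - native_window, tss + native_window
    )
    native_dist = None if native is None else int(abs(int(native[0]) - tss))
    if native_dist is not None and native_dist <= dist_fused:
        return None
    return EnhancerTranslocationCall(
        ssv_id=ssv.ssv_id,
        gene_id=gene.gene_id,
        tumor_id=ssv.tumor_id,
        translocated_enhancer=(mate_chrom, int(fused[1]), int(fused[2])),
        distance_to_breakend=dist_fused,
        native_enhancer_distance=native_dist,
    )


def scan_enhancer_translocations(
    ssvs: Sequence[SSVRecord],
    genes: Sequence[GeneAnnotation],
    enhancers: IntervalSet,
    max_fused: int = DEFAULT_FUSED_WINDOW,
    native_window: int = DEFAULT_NATIVE_WINDOW,
    proximal_window: int = DEFAULT_PROXIMAL_WINDOW,
) -> list[EnhancerTranslocationCall]:
    """Cohort-wide scan: per (gene, tumor) only the breakend closest to
    the TSS is considered, and duplicate calls keep the closest
    translocated enhancer."""
    mids = _enhancer_midpoints(enhancers)
    by_tumor: dict[str, list[SSVRecord]] = {}
    for s in ssvs:
        by_tumor.setdefault(s.tumor_id, []).append(s)

    calls: dict[tuple[str, str], EnhancerTranslocationCall] = {}
    for gene in genes:
        tss = gene.tss
        for tumor, records in by_tumor.items():
            best: tuple[int, SSVRecord] | None = None
            for s in records:
                for chrom, pos, orient in s.breakends:
                    if _proximal_qualifies(gene, chrom, pos, orient, proximal_window):
                        d = abs(pos - tss)
                        if best is None or d < best[0]:
                            best = (d, s)
            if best is None:
                continue
            call = detect_enhancer_translocation(
                best[1], gene, mids, max_fused, native_window, proximal_window
            )
            if call is None:
                continue
            key = (gene.gene_id, tumor)
            prev = calls.get(key)
            if prev is None or call.distance_to_breakend < prev.distance_to_breakend:
                calls[key] = call
    return sorted(calls.values(), key=lambda c: (c.gene_id, c.tumor_id))


def cna_ssv_enrichment(
    presence_1mb: BreakpointPresenceMatrix,
    cna: pd.DataFrame,
    level: int,
) -> dict:
    """Chi-squared association of (breakpoint within window) x (CNA at
    ``level``) over all aligned gene x tumor pairs."""
    if level not in (2, -2):
        raise ValueError("level must be +2 (amplification) or -2 (deep deletion)")
    genes = [g for g in presence_1mb.values.index if g in set(cna.index)]
    tumors = [t for t in presence_1mb.values.columns if t in set(cna.columns)]
    bp = presence_1mb.values.loc[genes, tumors].to_numpy().ravel() == 1
    cn = cna.loc[genes, tumors].to_numpy().ravel() == level
    both = int(np.sum(bp & cn))
    table = np.asarray(
        [
            [both, int(np.sum(bp & ~cn))],
            [int(np.sum(~bp & cn)), int(np.sum(~bp & ~cn))],
        ]
    )
    if cn.sum() == 0 or bp.sum() == 0:
        warnings.warn("cna_ssv_enrichment: degenerate margins, p set to 1", stacklevel=2)
        return {"chi2": np.nan, "p_value": 1.0, "n_both": both, "table": table}
    chi2, p, fisher = _two_by_two_chi2(table)
    return {"chi2": chi2, "p_value": p, "n_both": both, "table": table,
            "fisher_fallback": fisher}


def altered_ssv_ids(
    ssvs: Sequence[SSVRecord],
    genes: Sequence[GeneAnnotation],
    assoc: pd.DataFrame,
    sd_scores: pd.DataFrame,
    q_threshold: float = 0.10,
    sd_threshold: float = 0.4,
    window: int = 1_000_000,
) -> set[str]:
    """SSVs whose breakends lie within ``window`` of the TSS of an
    FDR-significant gene in a tumor where that gene's expression is
    shifted beyond ``sd_threshold`` in the direction of the association."""
    sig = assoc[(assoc["q_storey"] < q_threshold) & (assoc["p_value"].notna())]
    directions = dict(zip(sig["gene_id"], sig["direction"]))
    gene_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        if g.gene_id in directions:
            gene_by_chrom.setdefault(g.chrom, []).append(g)

    out: set[str] = set()
    for s in ssvs:
        for chrom, pos, _ in s.breakends:
            for g in gene_by_chrom.get(chrom, []):
                if abs(pos - g.tss) > window:
                    continue
                if g.gene_id not in sd_scores.index or s.tumor_id not in sd_scores.columns:
                    continue
                score = sd_scores.loc[g.gene_id, s.tumor_id]
                if pd.isna(score):
                    continue
                wanted = directions[g.gene_id]
                if (wanted == "positive" and score > sd_threshold) or (
                    wanted == "negative" and score < -sd_threshold
                ):
                    out.add(s.ssv_id)
                    break
            else:
                continue
            break
    return out
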