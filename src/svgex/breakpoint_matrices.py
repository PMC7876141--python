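"""Gene x tumor breakpoint predictors.

Two predictor constructions are supported: binary presence of at least
one breakend within a window around each gene, and the log2 distance
from each gene's TSS to the nearest breakend within +/-1 Mb (imputed at
the maximum when no breakend is close enough).  Both breakends of every
SSV are treated as independent breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, SSVRecord

MAX_DISTANCE_BP = 1_000_000

WINDOW_REGIONS = ("gene_body", "upstream", "downstream", "symmetric")


@dataclass(frozen=True)
class WindowSpec:
    """A genomic region window relative to a gene.

    ``upstream`` extends from the gene start away from the gene body;
    ``downstream`` extends from the far end of the gene; ``symmetric``
    is centered on the TSS.  All are resolved strand-aware.
    """

    region: str = "gene_body"
    extent: int = 100_000
    strand_aware: bool = True

    def __post_init__(self) -> None:
        if self.region not in WINDOW_REGIONS:
            raise ValueError(f"unknown window region {self.region!r}")
        if self.region != "gene_body" and self.extent <= 0:
            raise ValueError("window extent must be positive")

    def bounds(self, gene: GeneAnnotation) -> tuple[int, int]:
        """Half-open [lo, hi) window for ``gene`` on its chromosome."""
        if self.region == "gene_body":
            return gene.start, gene.end
        fwd = gene.strand == "+" or not self.strand_aware
        if self.region == "upstream":
            if fwd:
                return gene.start - self.extent, gene.start
            return gene.end, gene.end + self.extent
        if self.region == "downstream":
            if fwd:
                return gene.end, gene.end + self.extent
            return gene.start - self.extent, gene.start
        # symmetric around the TSS
        return gene.tss - self.extent, gene.tss + self.extent + 1


@dataclass
class BreakpointPresenceMatrix:
    values: pd.DataFrame  # genes x tumors, int8 in {0,1}
    window: WindowSpec


@dataclass
class DistanceMatrix:
    """log2 distance from TSS to nearest breakend, imputed at ``max_dist``."""

    values: pd.DataFrame  # genes x tumors, float
    imputed: pd.DataFrame  # genes x tumors, bool
    max_dist: int = MAX_DISTANCE_BP


def _breakend_index(
    ssvs: Iterable[SSVRecord], tumors: Sequence[str]
) -> dict[tuple[str, str], np.ndarray]:
    """Sorted breakend positions keyed by (tumor_id, chrom)."""
    pos: dict[tuple[str, str], list[int]] = {}
    tumor_set = set(tumors)
    for s in ssvs:
        if s.tumor_id not in tumor_set:
            raise ValueError(f"SSV {s.ssv_id}: tumor {s.tumor_id!r} not in tumor set")
        pos.setdefault((s.tumor_id, s.chrom1), []).append(s.pos1)
        pos.setdefault((s.tumor_id, s.chrom2), []).append(s.pos2)
    return {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in pos.items()}


def build_presence_matrix(
    ssvs: Sequence[SSVRecord],
    genes: Sequence[GeneAnnotation],
    tumors: Sequence[str],
    window: WindowSpec,
) -> BreakpointPresenceMatrix:
    """1 iff >=1 breakend of any SSV of the tumor lies in the gene's window."""
    index = _breakend_index(ssvs, tumors)
    gene_ids = [g.gene_id for g in genes]
    out = np.zeros((len(genes), len(tumors)), dtype=np.int8)

    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    bounds = np.asarray([window.bounds(g) for g in genes], dtype=np.int64) if genes else None

    for t_idx, tumor in enumerate(tumors):
        for chrom, g_idx in by_chrom.items():
            positions = index.get((tumor, chrom))
            if positions is None or len(positions) == 0:
                continue
            gi = np.asarray(g_idx)
            lo = bounds[gi, 0]
            hi = bounds[gi, 1]
            n_in = np.searchsorted(positions, hi, side="left") - np.searchsorted(
                positions, lo, side="left"
            )
            out[gi, t_idx] = (n_in > 0).astype(np.int8)

    df = pd.DataFrame(out, index=gene_ids, columns=list(tumors))
    return BreakpointPresenceMatrix(values=df, window=window)


def build_distance_matrix(
    ssvs: Sequence[SSVRecord],
    genes: Sequence[GeneAnnotation],
    tumors: Sequence[str],
    max_dist: int = MAX_DISTANCE_BP,
) -> DistanceMatrix:
    """Per (gene, tumor) log2 of the nearest-breakend distance to the TSS.

    Distances beyond ``max_dist`` (or absent breakends) are imputed at
    ``max_dist``; distances are clipped below at 1 bp before log2.
    """
    index = _breakend_index(ssvs, tumors)
    gene_ids = [g.gene_id for g in genes]
    dist = np.full((len(genes), len(tumors)), float(max_dist))

    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    tss = np.asarray([g.tss for g in genes], dtype=np.int64) if genes else None

    for t_idx, tumor in enumerate(tumors):
        for chrom, g_idx in by_chrom.items():
            positions = index.get((tumor, chrom))
            if positions is None or len(positions) == 0:
                continue
            gi = np.asarray(g_idx)
            t = tss[gi]
            right = np.searchsorted(positions, t, side="left")
            left = right - 1
            d_right = np.where(
                right < len(positions), positions[np.minimum(right, len(positions) - 1)] - t,
                np.iinfo(np.int64).max,
            )
            d_left = np.where(left >= 0, t - positions[np.maximum(left, 0)], np.iinfo(np.int64).max)
            nearest = np.minimum(np.abs(d_right), np.abs(d_left))
            dist[gi, t_idx] = np.minimum(nearest, max_dist)

    imputed = dist >= max_dist
    values = np.log2(np.clip(dist, 1.0, None))
    values[imputed] = np.log2(max_dist)

    idx = pd.Index(gene_ids)
    cols = list(tumors)
    return DistanceMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        imputed=pd.DataFrame(imputed, index=idx, columns=cols),
        max_dist=max_dist,
    )


def count_ssv_burden(
    ssvs: Iterable[SSVRecord], tumors: Sequence[str] | None = None
) -> pd.Series:
    """Per-tumor SSV counts (mate-merged records each count once)."""
    counts: dict[str, int] = {t: 0 for t in tumors} if tumors is not None else {}
    for s in ssvs:
        if tumors is not None and s.tumor_id not in counts:
            raise ValueError(f"SSV {s.ssv_id}: tumor {s.tumor_id!r} not in tumor set")
        counts[s.tumor_id] = counts.get(s.tumor_id, 0) + 1
    return pd.Series(counts, dtype=np.int64).rename("ssv_count")
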