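"""Readers and writers for the external formats the pipeline touches.

Coordinate contract: all positions are stored 0-based; intervals are
half-open ``[start, end)``.  VCF input (1-based) is converted on read.
Breakend orientation records which side of a breakpoint is retained in
the derivative chromosome: ``positive`` keeps the sequence upstream
(lower coordinates) of the breakend, ``negative`` keeps the downstream
side.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SV_CLASSES = ("deletion", "duplication", "insertion", "inversion", "translocation")
ORIENTATIONS = ("positive", "negative")
TUMOR_STATUSES = ("initial", "progressive", "recurrent", "second_malignancy")

_CANONICAL_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2]|X|Y)$")

_SVTYPE_MAP = {
    "DEL": "deletion",
    "DUP": "duplication",
    "DUP:TANDEM": "duplication",
    "INS": "insertion",
    "INV": "inversion",
}

# breakend orientation conventions for symmetric (non-BND) SV records
_SIMPLE_ORIENTS = {
    "deletion": ("positive", "negative"),
    "duplication": ("negative", "positive"),
    "inversion": ("positive", "positive"),
    "insertion": ("positive", "negative"),
}

_BND_ALT_RE = re.compile(
    r"^([ACGTNacgtn]*)([\[\]])([^\[\]:]+):([0-9]+)([\[\]])([ACGTNacgtn]*)$"
)


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


@dataclass(frozen=True)
class SSVRecord:
    """A single somatic structural variant with two breakends."""

    ssv_id: str
    svclass: str
    chrom1: str
    pos1: int
    orient1: str
    chrom2: str
    pos2: int
    orient2: str
    tumor_id: str
    pass_filter: bool = True

    def __post_init__(self) -> None:
        if self.svclass not in SV_CLASSES:
            raise ValueError(f"unknown svclass {self.svclass!r}")
        if self.orient1 not in ORIENTATIONS or self.orient2 not in ORIENTATIONS:
            raise ValueError("orientation must be 'positive' or 'negative'")
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError("breakend positions must be non-negative")
        if (self.chrom1 != self.chrom2) != (self.svclass == "translocation"):
            raise ValueError(
                "svclass must be 'translocation' iff chromosomes differ "
                f"(got {self.svclass} on {self.chrom1}/{self.chrom2})"
            )

    @property
    def breakends(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return (
            (self.chrom1, self.pos1, self.orient1),
            (self.chrom2, self.pos2, self.orient2),
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene span with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class TumorMeta:
    tumor_id: str
    patient_id: str
    tumor_type: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in TUMOR_STATUSES:
            raise ValueError(f"unknown tumor status {self.status!r}")


@dataclass
class IntervalSet:
    """Named set of sorted genomic intervals (0-based half-open)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise ValueError(
                    f"{self.name}: interval {chrom}:{start}-{end} has start >= end"
                )
        self.intervals = sorted(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of starts/ends."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def is_canonical_chrom(name: str) -> bool:
    return bool(_CANONICAL_RE.match(name))


def _chrom_sort_key(chrom: str, pos: int) -> tuple[str, int]:
    return (chrom, pos)


def _ordered(chrom1, pos1, o1, chrom2, pos2, o2):
    if _chrom_sort_key(chrom2, pos2) < _chrom_sort_key(chrom1, pos1):
        return chrom2, pos2, o2, chrom1, pos1, o1
    return chrom1, pos1, o1, chrom2, pos2, o2


def _intra_class(orient_low: str, orient_high: str) -> str:
    if orient_low == "positive" and orient_high == "negative":
        return "deletion"
    if orient_low == "negative" and orient_high == "positive":
        return "duplication"
    return "inversion"


def _parse_bnd_alt(alt: str):
    m = _BND_ALT_RE.match(alt)
    if m is None:
        return None
    prefix, b1, mate_chrom, mate_pos, b2, suffix = m.groups()
    if b1 != b2:
        return None
    # leading inserted/ref base => sequence left of this breakend is retained
    orient_here = "positive" if prefix else "negative"
    # ']' points at sequence left of the mate position; '[' at the right side
    orient_mate = "positive" if b1 == "]" else "negative"
    return mate_chrom, int(mate_pos), orient_here, orient_mate


def read_sv_vcf(path: str | Path, tumor_id: str, pass_only: bool = True) -> list[SSVRecord]:
    """Read Manta-style SV calls from a VCF into merged :class:`SSVRecord` s.

    BND mate pairs are merged into a single record spanning both
    breakends, so a translocation contributes one record.  Non-PASS
    records are dropped when ``pass_only``.  Records on non-canonical
    chromosomes are dropped with a logged count.
    """
    import pysam

    records: list[SSVRecord] = []
    bnds: dict[str, tuple] = {}  # id -> (chrom, pos0, orient, mate_chrom, mate_pos0, mate_orient, mate_id)
    bnd_order: list[str] = []
    n_noncanonical = 0
    counter = 0

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if pass_only and len(rec.filter) > 0 and "PASS" not in rec.filter:
                continue
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            if rec.pos is None or rec.pos < 1:
                raise FormatError(f"{path}: malformed position for record {rec.id}")
            chrom1, pos1 = rec.chrom, rec.pos - 1  # to 0-based
            if svtype == "BND":
                alt = rec.alts[0] if rec.alts else ""
                parsed = _parse_bnd_alt(alt)
                if parsed is None:
                    raise FormatError(f"{path}: malformed BND ALT {alt!r} for record {rec.id}")
                mate_chrom, mate_pos1b, orient_here, orient_mate = parsed
                mate_ids = rec.info.get("MATEID")
                mate_id = mate_ids[0] if isinstance(mate_ids, tuple) else mate_ids
                rid = rec.id or f"bnd{len(bnd_order)}"
                bnds[rid] = (chrom1, pos1, orient_here, mate_chrom, mate_pos1b - 1, orient_mate, mate_id)
                bnd_order.append(rid)
            else:
                svclass = _SVTYPE_MAP.get(svtype)
                if svclass is None:
                    continue
                end = rec.info.get("END", rec.stop)
                if end is None or int(end) < 1:
                    raise FormatError(f"{path}: missing/invalid END for record {rec.id}")
                pos2 = int(end) - 1
                if not is_canonical_chrom(chrom1):
                    n_noncanonical += 1
                    continue
                o1, o2 = _SIMPLE_ORIENTS[svclass]
                counter += 1
                records.append(
                    SSVRecord(
                        ssv_id=rec.id or f"ssv{counter}", svclass=svclass,
                        chrom1=chrom1, pos1=min(pos1, pos2), orient1=o1,
                        chrom2=chrom1, pos2=max(pos1, pos2), orient2=o2,
                        tumor_id=tumor_id, pass_filter=True,
                    )
                )

    consumed: set[str] = set()
    n_unpaired = 0
    for rid in bnd_order:
        if rid in consumed:
            continue
        chrom1, pos1, o1, chrom2, pos2, o2, mate_id = bnds[rid]
        if mate_id is None or mate_id not in bnds:
            n_unpaired += 1
            consumed.add(rid)
            continue
        consumed.add(rid)
        consumed.add(mate_id)
        c1, p1, oo1, c2, p2, oo2 = _ordered(chrom1, pos1, o1, chrom2, pos2, o2)
        if not (is_canonical_chrom(c1) and is_canonical_chrom(c2)):
            n_noncanonical += 1
            continue
        svclass = "translocation" if c1 != c2 else _intra_class(oo1, oo2)
        records.append(
            SSVRecord(
                ssv_id=rid, svclass=svclass,
                chrom1=c1, pos1=p1, orient1=oo1,
                chrom2=c2, pos2=p2, orient2=oo2,
                tumor_id=tumor_id, pass_filter=True,
            )
        )

    if n_unpaired:
        warnings.warn(
            f"{path}: dropped {n_unpaired} unpaired BND mate record(s)", stacklevel=2
        )
    if n_noncanonical:
        logger.info("%s: dropped %d record(s) on non-canonical chromosomes", path, n_noncanonical)
    return records


_STRAND_FROM_ORIENT = {"positive": "+", "negative": "-"}
_ORIENT_FROM_STRAND = {"+": "positive", "-": "negative"}

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "svclass", "tumor_id", "pass_filter",
]


def write_bedpe(records: Iterable[SSVRecord], path: str | Path) -> None:
    """Write SSV records as 10+3 column BEDPE (strand cols encode orientation)."""
    rows = []
    for r in records:
        rows.append(
            (
                r.chrom1, r.pos1, r.pos1 + 1, r.chrom2, r.pos2, r.pos2 + 1,
                r.ssv_id, ".",
                _STRAND_FROM_ORIENT[r.orient1], _STRAND_FROM_ORIENT[r.orient2],
                r.svclass, r.tumor_id, int(r.pass_filter),
            )
        )
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path: str | Path) -> list[SSVRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=BEDPE_COLUMNS,
        dtype={"chrom1": str, "chrom2": str, "name": str, "tumor_id": str},
    )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SSVRecord(
                ssv_id=str(row.name),
                svclass=row.svclass,
                chrom1=str(row.chrom1),
                pos1=int(row.start1),
                orient1=_ORIENT_FROM_STRAND[row.strand1],
                chrom2=str(row.chrom2),
                pos2=int(row.start2),
                orient2=_ORIENT_FROM_STRAND[row.strand2],
                tumor_id=str(row.tumor_id),
                pass_filter=bool(int(row.pass_filter)),
            )
        )
    return out


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a genes x tumors TSV matrix.

    ``kind='cna'`` enforces thresholded values in {-2,-1,0,1,2};
    ``kind='mutation'`` enforces {0,1}; ``kind='expression'`` allows
    floats and records genes with missing cells in
    ``df.attrs['genes_with_missing']``.
    """
    if kind not in ("expression", "cna", "mutation"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene row(s): {dups}")
    if kind in ("cna", "mutation"):
        allowed = {-2, -1, 0, 1, 2} if kind == "cna" else {0, 1}
        values = df.to_numpy()
        bad = ~np.isin(values, list(allowed)) | pd.isna(values)
        if bad.any():
            gi, ti = np.argwhere(bad)[0]
            raise FormatError(
                f"{path}: invalid {kind} value {values[gi, ti]!r} for gene "
                f"{df.index[gi]!r}, tumor {df.columns[ti]!r}"
            )
        df = df.astype(np.int64)
    else:
        df = df.astype(float)
        missing = df.index[df.isna().any(axis=1)].tolist()
        df.attrs["genes_with_missing"] = missing
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean order-statistic distribution.

    Ties within a column receive the average of the target values over
    the tied ranks.  Rows with missing values are excluded from the
    computation and returned as-is.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged", stacklevel=2)
        return matrix.copy()
    complete = ~matrix.isna().any(axis=1)
    sub = matrix.loc[complete]
    values = sub.to_numpy(dtype=float)
    order = np.argsort(values, axis=0, kind="mergesort")
    target = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col_order = order[:, j]
        sorted_col = values[col_order, j]
        assigned = target.copy()
        # average the target over runs of tied input values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                assigned[s:e] = target[s:e].mean()
        out[col_order, j] = assigned

    result = matrix.copy()
    result.loc[complete] = out
    return result


def read_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3(+) file into an :class:`IntervalSet`."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    intervals = [
        (str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples(index=False)
    ]
    return IntervalSet(name=name or Path(path).stem, intervals=intervals)


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in iset.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotation from BED6 (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str},
    )
    genes = [
        GeneAnnotation(
            gene_id=str(r.gene_id), chrom=str(r.chrom),
            start=int(r.start), end=int(r.end), strand=str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate gene_id values")
    return genes


def write_genes_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_tumor_meta(path: str | Path) -> list[TumorMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tumor_id", "patient_id", "tumor_type", "status"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: tumor metadata must have columns {sorted(required)}")
    metas = [
        TumorMeta(r.tumor_id, r.patient_id, r.tumor_type, r.status)
        for r in df.itertuples(index=False)
    ]
    ids = [m.tumor_id for m in metas]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate tumor_id values")
    return metas


def write_tumor_meta(metas: Sequence[TumorMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.tumor_id, m.patient_id, m.tumor_type, m.status) for m in metas],
        columns=["tumor_id", "patient_id", "tumor_type", "status"],
    ).to_csv(path, sep="\t", index=False)


def read_fusion_candidates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b", "tumor_id", "caller"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: fusion table must have columns {sorted(required)}")
    return df


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like mutation table (gene, tumor_id, consequence, hotspot)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "tumor_id", "consequence", "hotspot"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: mutation table must have columns {sorted(required)}")
    df["hotspot"] = df["hotspot"].astype(bool)
    return df


def read_banned_pairs(path: str | Path) -> set[frozenset[str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_a", "gene_b"], dtype=str)
    return {frozenset((r.gene_a, r.gene_b)) for r in df.itertuples(index=False)}
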