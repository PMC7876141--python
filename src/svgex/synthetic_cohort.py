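"""Synthetic tumor cohorts with a ground-truth manifest.

Generates an SV call set, raw expression matrix, thresholded CNA
matrix, tumor metadata, mutation table, and fusion candidate table with
the statistical structure the analysis pipeline assumes: heavy-tailed
per-tumor SSV burden, SSV-CNA coupling via duplications, planted
cis-effect genes with breakends near the TSS, planted CNA-dosage-only
genes (the confounder the CNA covariate must absorb), planted fusions
as gene-body breakend pairs with expression bumps, and a burden-linked
inactivating-mutation driver.

Expression is generated on log2 scale and exponentiated for the raw
matrix so that the pipeline's ``log2(x + 1)`` transform recovers it
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GeneAnnotation,
    IntervalSet,
    SSVRecord,
    TumorMeta,
    write_bed,
    write_bedpe,
    write_genes_bed,
    write_matrix,
    write_tumor_meta,
)

TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CohortParams:
    """Knobs for cohort generation.  ``seed`` is mandatory."""

    seed: int
    n_tumors: int = 150
    n_types: int = 3
    n_genes: int = 500
    n_chromosomes: int = 16
    chrom_length: int = 120_000_000

    # per-tumor SSV burden: median * exp(sigma * Z), heavy right tail
    burden_median: float = 47.0
    burden_sigma: float = 1.0
    type_burden_spread: float = 0.3
    svclass_mix: tuple[tuple[str, float], ...] = (
        ("deletion", 0.30),
        ("duplication", 0.25),
        ("inversion", 0.15),
        ("insertion", 0.05),
        ("translocation", 0.25),
    )

    # planted cis-effect genes
    planted_cis_genes: int = 0
    cis_effect_sd: float = 1.5
    cis_carriers: int = 10
    cis_breakend_offset: int = 10_000

    # CNA structure
    cna_coupling: float = 0.4  # P(duplication emits a spanning CNA gain)
    cna_background_rate: float = 0.01
    cna_dosage_effect: float = 0.8  # log2 units per thresholded step
    planted_cna_genes: int = 0
    cna_carriers: int = 10

    # fusions
    planted_fusions: int = 0
    fusion_expr_bump: float = 1.5  # in units of noise SD
    n_decoy_fusions: int = 4
    n_banned_fusions: int = 3
    n_same_gene_fusions: int = 2

    # burden correlates
    planted_burden_driver: bool = False
    burden_driver_slope: float = 4.0  # logit slope per log10 burden unit
    n_mutation_genes: int = 20
    mutation_rate: float = 0.03
    burden_expr_genes: int = 0
    burden_expr_slope: float = 0.8  # log2 units per log10(count+1)

    # paired initial/advanced design
    n_pairs: int = 0
    recurrent_burden_factor: float = 1.5

    # expression model
    baseline_mean: float = 8.0
    baseline_spread: float = 2.0
    type_spread: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_tumors < 1 or self.n_genes < 0 or self.n_chromosomes < 1:
            raise ValueError("cohort dimensions must be positive")
        reserved = (
            self.planted_cis_genes
            + self.planted_cna_genes
            + self.burden_expr_genes
            + 2 * self.planted_fusions
        )
        if reserved > self.n_genes:
            raise ValueError("more planted genes requested than genes available")
        if self.n_pairs * 2 > self.n_tumors:
            raise ValueError("n_pairs requires 2 tumors each")
        if not np.isfinite(self.cis_effect_sd):
            raise ValueError("effect sizes must be finite")


@dataclass
class SyntheticTruth:
    """Manifest of every planted signal, for parameter-recovery tests."""

    cis_genes: dict[str, dict] = field(default_factory=dict)
    cna_only_genes: dict[str, list[str]] = field(default_factory=dict)
    burden_expr_genes: dict[str, float] = field(default_factory=dict)
    fusions: list[dict] = field(default_factory=list)
    burden_driver: str | None = None
    true_burden: dict[str, int] = field(default_factory=dict)
    banned_pairs: list[list[str]] = field(default_factory=list)
    schema_version: int = TRUTH_SCHEMA_VERSION

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticCohort:
    params: CohortParams
    genes: list[GeneAnnotation]
    tads: IntervalSet
    enhancers: IntervalSet
    ssvs: list[SSVRecord]
    expression: pd.DataFrame  # raw scale, genes x tumors
    cna: pd.DataFrame
    meta: list[TumorMeta]
    mutations: pd.DataFrame  # MAF-like
    fusions: pd.DataFrame
    banned: set[frozenset[str]]
    truth: SyntheticTruth

    @property
    def tumors(self) -> list[str]:
        return [m.tumor_id for m in self.meta]

    def mutation_matrix(self, inactivating_only: bool = True) -> pd.DataFrame:
        """Binary genes x tumors mutation indicator matrix."""
        rows = self.mutations
        if inactivating_only:
            keep = rows["consequence"].str.lower().isin(
                ["nonsense", "nonstop", "indel", "frameshift_indel"]
            )
            rows = rows[keep]
        genes = sorted(rows["gene"].unique())
        mat = pd.DataFrame(0, index=genes, columns=self.tumors, dtype=np.int64)
        for row in rows.itertuples(index=False):
            mat.loc[row.gene, row.tumor_id] = 1
        return mat

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bedpe(self.ssvs, outdir / "sv.bedpe")
        write_matrix(self.expression, outdir / "expression.tsv")
        write_matrix(self.cna, outdir / "cna.tsv")
        write_tumor_meta(self.meta, outdir / "meta.tsv")
        self.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
        self.fusions.to_csv(outdir / "fusions.tsv", sep="\t", index=False)
        with open(outdir / "banned.tsv", "w") as fh:
            for pair in sorted(tuple(sorted(p)) for p in self.banned):
                fh.write(f"{pair[0]}\t{pair[1]}\n")
        write_genes_bed(self.genes, outdir / "genes.bed")
        write_bed(self.tads, outdir / "tads.bed")
        write_bed(self.enhancers, outdir / "enhancers.bed")
        self.truth.to_json(outdir / "truth.json")


def generate_annotation(
    params: CohortParams, rng: np.random.Generator | None = None
) -> tuple[list[GeneAnnotation], IntervalSet, IntervalSet]:
    """Non-overlapping genes, tiling TADs, and enhancer intervals."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_chrom = params.n_chromosomes
    per_chrom = -(-params.n_genes // n_chrom)  # ceil
    slot = params.chrom_length // (per_chrom + 1)
    if params.n_genes and slot < 30_000:
        raise ValueError(
            f"cannot pack {params.n_genes} genes into {n_chrom} chromosomes "
            f"of {params.chrom_length} bp at >=10 kb spacing"
        )
    genes: list[GeneAnnotation] = []
    gi = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        for s in range(per_chrom):
            if gi >= params.n_genes:
                break
            jitter = int(rng.integers(-slot // 4, slot // 4 + 1))
            start = (s + 1) * slot + jitter
            length = int(rng.integers(5_000, min(50_000, slot // 2)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(
                    gene_id=f"G{gi + 1:05d}", chrom=chrom,
                    start=start, end=start + length, strand=strand,
                )
            )
            gi += 1

    tad_intervals: list[tuple[str, int, int]] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        pos = 0
        while pos < params.chrom_length:
            width = int(rng.integers(600_000, 1_200_000))
            end = min(pos + width, params.chrom_length)
            tad_intervals.append((chrom, pos, end))
            gap = int(rng.integers(0, 40_000)) if rng.random() < 0.3 else 0
            pos = end + gap
    tads = IntervalSet("tads", tad_intervals)

    enh_intervals: list[tuple[str, int, int]] = []
    for g in genes:
        if rng.random() < 0.5:
            offset = int(rng.integers(50_000, 800_000)) * (1 if rng.random() < 0.5 else -1)
            mid = g.tss + offset
            if 1_000 < mid < params.chrom_length - 1_000:
                enh_intervals.append((g.chrom, mid - 500, mid + 500))
    n_desert = max(5, params.n_genes // 10)
    for _ in range(n_desert):
        chrom = f"chr{int(rng.integers(0, n_chrom)) + 1}"
        mid = int(rng.integers(1_000, params.chrom_length - 1_000))
        enh_intervals.append((chrom, mid - 500, mid + 500))
    enhancers = IntervalSet("enhancers", enh_intervals)
    return genes, tads, enhancers


def _make_meta(params: CohortParams, rng: np.random.Generator) -> list[TumorMeta]:
    types = [f"type{k + 1}" for k in range(params.n_types)]
    metas: list[TumorMeta] = []
    t_idx = 0
    for p in range(params.n_pairs):
        ttype = types[int(rng.integers(0, params.n_types))]
        pid = f"P{p + 1:04d}"
        for status in ("initial", "progressive"):
            metas.append(TumorMeta(f"T{t_idx + 1:04d}", pid, ttype, status))
            t_idx += 1
    p_idx = params.n_pairs
    while t_idx < params.n_tumors:
        ttype = types[int(rng.integers(0, params.n_types))]
        metas.append(TumorMeta(f"T{t_idx + 1:04d}", f"P{p_idx + 1:04d}", ttype, "initial"))
        t_idx += 1
        p_idx += 1
    return metas


def _random_ssv(ssv_id, tumor_id, svclass, params, rng) -> SSVRecord:
    n_chrom = params.n_chromosomes
    L = params.chrom_length
    if svclass == "translocation":
        c1, c2 = rng.choice(n_chrom, size=2, replace=False)
        chrom1, chrom2 = f"chr{c1 + 1}", f"chr{c2 + 1}"
        pos1 = int(rng.integers(0, L))
        pos2 = int(rng.integers(0, L))
        o1 = "positive" if rng.random() < 0.5 else "negative"
        o2 = "positive" if rng.random() < 0.5 else "negative"
        if (chrom2, pos2) < (chrom1, pos1):
            chrom1, pos1, o1, chrom2, pos2, o2 = chrom2, pos2, o2, chrom1, pos1, o1
        return SSVRecord(ssv_id, svclass, chrom1, pos1, o1, chrom2, pos2, o2, tumor_id)
    chrom = f"chr{int(rng.integers(0, n_chrom)) + 1}"
    if svclass == "insertion":
        size = int(rng.integers(10, 500))
    else:
        size = int(10 ** rng.uniform(3.0, 6.0))
    pos1 = int(rng.integers(0, max(1, L - size)))
    pos2 = pos1 + size
    orients = {
        "deletion": ("positive", "negative"),
        "duplication": ("negative", "positive"),
        "inversion": ("positive", "positive"),
        "insertion": ("positive", "negative"),
    }[svclass]
    return SSVRecord(ssv_id, svclass, chrom, pos1, orients[0], chrom, pos2, orients[1], tumor_id)


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Generate a full synthetic cohort plus its truth manifest."""
    rng = np.random.default_rng(params.seed)
    genes, tads, enhancers = generate_annotation(params, rng)
    metas = _make_meta(params, rng)
    tumors = [m.tumor_id for m in metas]
    n_genes, n_tumors = len(genes), len(tumors)
    gene_ids = [g.gene_id for g in genes]
    gene_by_id = {g.gene_id: g for g in genes}
    truth = SyntheticTruth()

    classes = [c for c, _ in params.svclass_mix]
    probs = np.asarray([w for _, w in params.svclass_mix])
    probs = probs / probs.sum()

    # --- per-tumor burden (heavy-tailed, type-shifted, advanced inflated)
    types = sorted({m.tumor_type for m in metas})
    type_factor = {
        t: float(np.exp(rng.normal(0.0, params.type_burden_spread))) for t in types
    }
    counts: dict[str, int] = {}
    for m in metas:
        lam = params.burden_median * np.exp(params.burden_sigma * rng.normal()) * type_factor[m.tumor_type]
        if m.status in ("progressive", "recurrent"):
            lam *= params.recurrent_burden_factor
        counts[m.tumor_id] = max(0, int(round(lam)))

    # --- background SSVs
    ssvs: list[SSVRecord] = []
    sid = 0
    for m in metas:
        for _ in range(counts[m.tumor_id]):
            sid += 1
            svclass = classes[int(rng.choice(len(classes), p=probs))]
            ssvs.append(_random_ssv(f"SSV{sid:07d}", m.tumor_id, svclass, params, rng))

    # --- reserve planted genes disjointly
    perm = rng.permutation(n_genes)
    cursor = 0
    cis_idx = perm[cursor:cursor + params.planted_cis_genes]; cursor += params.planted_cis_genes
    cna_idx = perm[cursor:cursor + params.planted_cna_genes]; cursor += params.planted_cna_genes
    bexpr_idx = perm[cursor:cursor + params.burden_expr_genes]; cursor += params.burden_expr_genes
    fusion_idx = perm[cursor:cursor + 2 * params.planted_fusions]

    cna = np.zeros((n_genes, n_tumors), dtype=np.int64)
    gene_tss = np.asarray([g.tss for g in genes])
    gene_chrom = np.asarray([g.chrom for g in genes])

    # --- background CNA noise
    noise_mask = rng.random((n_genes, n_tumors)) < params.cna_background_rate
    noise_vals = rng.choice([-2, -1, 1, 2], size=noise_mask.sum(), p=[0.05, 0.45, 0.45, 0.05])
    cna[noise_mask] = noise_vals

    # --- SSV-CNA coupling: duplications emit spanning gains
    for s in ssvs:
        if s.svclass != "duplication" or rng.random() >= params.cna_coupling:
            continue
        span = (gene_chrom == s.chrom1) & (gene_tss >= s.pos1) & (gene_tss < s.pos2)
        if span.any():
            gain = 2 if rng.random() < 0.2 else 1
            cna[span, tumors.index(s.tumor_id)] = gain

    # --- planted cis-effect genes: breakends near the TSS + expression shift
    cis_effect = np.zeros((n_genes, n_tumors))
    for gi in cis_idx:
        g = genes[gi]
        carriers = rng.choice(n_tumors, size=params.cis_carriers, replace=False)
        carrier_ids = [tumors[i] for i in carriers]
        for ti in carriers:
            sid += 1
            off = int(rng.integers(-params.cis_breakend_offset, params.cis_breakend_offset + 1))
            pos1 = max(0, g.tss + off)
            ssvs.append(
                SSVRecord(
                    f"SSV{sid:07d}", "deletion", g.chrom, pos1, "positive",
                    g.chrom, pos1 + 5_000, "negative", tumors[ti],
                )
            )
            cis_effect[gi, ti] += params.cis_effect_sd * params.noise_sd
        truth.cis_genes[g.gene_id] = {
            "effect_sd": params.cis_effect_sd,
            "carriers": carrier_ids,
        }

    # --- planted CNA-dosage-only genes: spanning duplication + gain, no
    #     direct expression term (dosage term below is the only signal)
    for gi in cna_idx:
        g = genes[gi]
        carriers = rng.choice(n_tumors, size=params.cna_carriers, replace=False)
        carrier_ids = [tumors[i] for i in carriers]
        for ti in carriers:
            sid += 1
            pos1 = max(0, g.start - int(rng.integers(5_000, 20_000)))
            pos2 = g.end + int(rng.integers(5_000, 20_000))
            ssvs.append(
                SSVRecord(
                    f"SSV{sid:07d}", "duplication", g.chrom, pos1, "negative",
                    g.chrom, pos2, "positive", tumors[ti],
                )
            )
            cna[gi, ti] = 2 if rng.random() < 0.5 else 1
        truth.cna_only_genes[g.gene_id] = carrier_ids

    # --- planted fusions: gene-body breakend pairs + candidate rows
    fusion_rows: list[tuple[str, str, str, str]] = []
    fpairs = [(int(fusion_idx[2 * i]), int(fusion_idx[2 * i + 1])) for i in range(params.planted_fusions)]
    fusion_bump = np.zeros((n_genes, n_tumors))
    for ga_i, gb_i in fpairs:
        ga, gb = genes[ga_i], genes[gb_i]
        ti = int(rng.integers(0, n_tumors))
        pos_a = int(rng.integers(ga.start, ga.end))
        pos_b = int(rng.integers(gb.start, gb.end))
        sid += 1
        if ga.chrom != gb.chrom:
            (c1, p1, g1), (c2, p2, g2) = sorted(
                [(ga.chrom, pos_a, ga), (gb.chrom, pos_b, gb)], key=lambda x: (x[0], x[1])
            )
            ssvs.append(
                SSVRecord(
                    f"SSV{sid:07d}", "translocation", c1, p1, "positive",
                    c2, p2, "negative", tumors[ti],
                )
            )
        else:
            lo, hi = sorted((pos_a, pos_b))
            ssvs.append(
                SSVRecord(
                    f"SSV{sid:07d}", "deletion", ga.chrom, lo, "positive",
                    ga.chrom, hi, "negative", tumors[ti],
                )
            )
        fusion_rows.append((ga.gene_id, gb.gene_id, tumors[ti], "both"))
        fusion_bump[ga_i, ti] += params.fusion_expr_bump * params.noise_sd
        fusion_bump[gb_i, ti] += params.fusion_expr_bump * params.noise_sd
        truth.fusions.append(
            {"gene_a": ga.gene_id, "gene_b": gb.gene_id, "tumor_id": tumors[ti]}
        )

    # decoy candidates: RNA-only, banned, and same-gene events
    banned: set[frozenset[str]] = set()
    if params.planted_fusions or params.n_decoy_fusions:
        for _ in range(params.n_decoy_fusions):
            ga_i, gb_i = rng.choice(n_genes, size=2, replace=False)
            fusion_rows.append(
                (gene_ids[ga_i], gene_ids[gb_i], tumors[int(rng.integers(0, n_tumors))], "caller1")
            )
        for _ in range(params.n_banned_fusions):
            ga_i, gb_i = rng.choice(n_genes, size=2, replace=False)
            banned.add(frozenset((gene_ids[ga_i], gene_ids[gb_i])))
            fusion_rows.append(
                (gene_ids[ga_i], gene_ids[gb_i], tumors[int(rng.integers(0, n_tumors))], "caller2")
            )
        for _ in range(params.n_same_gene_fusions):
            gi = int(rng.integers(0, n_genes))
            fusion_rows.append(
                (gene_ids[gi], gene_ids[gi], tumors[int(rng.integers(0, n_tumors))], "caller1")
            )
    truth.banned_pairs = sorted([sorted(p) for p in banned])

    # --- mutations: background genes + optional burden-linked driver
    lb = np.log10(np.asarray([counts[t] for t in tumors]) + 1.0)
    mut_rows: list[tuple[str, str, str, bool]] = []
    mut_gene_idx = rng.choice(
        [i for i in range(n_genes) if i not in set(cis_idx) | set(cna_idx)],
        size=min(params.n_mutation_genes, n_genes),
        replace=False,
    )
    driver_gene: str | None = None
    for j, gi in enumerate(mut_gene_idx):
        gene = gene_ids[gi]
        if params.planted_burden_driver and j == 0:
            driver_gene = gene
            logit = -1.8 + params.burden_driver_slope * (lb - lb.mean())
            p_mut = 1.0 / (1.0 + np.exp(-logit))
            hit = rng.random(n_tumors) < p_mut
            if hit.sum() < 3:  # guarantee testability of the driver
                hit[np.argsort(lb)[-3:]] = True
            for ti in np.flatnonzero(hit):
                mut_rows.append((gene, tumors[ti], "nonsense", False))
        else:
            hit = rng.random(n_tumors) < params.mutation_rate
            for ti in np.flatnonzero(hit):
                cons = "nonsense" if rng.random() < 0.7 else "missense"
                mut_rows.append((gene, tumors[ti], cons, False))
    truth.burden_driver = driver_gene

    # --- expression on log2 scale
    baseline = rng.normal(params.baseline_mean, params.baseline_spread, size=n_genes)
    type_names = sorted({m.tumor_type for m in metas})
    type_effects = rng.normal(0.0, params.type_spread, size=(n_genes, len(type_names)))
    type_col = np.asarray([type_names.index(m.tumor_type) for m in metas])
    z = (
        baseline[:, None]
        + type_effects[:, type_col]
        + params.cna_dosage_effect * cna
        + cis_effect
        + fusion_bump
        + rng.normal(0.0, params.noise_sd, size=(n_genes, n_tumors))
    )
    if params.burden_expr_genes:
        centered = lb - lb.mean()
        for gi in bexpr_idx:
            z[gi] += params.burden_expr_slope * centered
            truth.burden_expr_genes[gene_ids[gi]] = params.burden_expr_slope

    raw = np.power(2.0, z) - 1.0
    expression = pd.DataFrame(raw, index=gene_ids, columns=tumors)
    cna_df = pd.DataFrame(cna, index=gene_ids, columns=tumors)
    mutations = pd.DataFrame(mut_rows, columns=["gene", "tumor_id", "consequence", "hotspot"])
    fusions = pd.DataFrame(fusion_rows, columns=["gene_a", "gene_b", "tumor_id", "caller"])
    truth.true_burden = {t: int(c) for t, c in counts.items()}

    return SyntheticCohort(
        params=params, genes=genes, tads=tads, enhancers=enhancers, ssvs=ssvs,
        expression=expression, cna=cna_df, meta=metas, mutations=mutations,
        fusions=fusions, banned=banned, truth=truth,
    )
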