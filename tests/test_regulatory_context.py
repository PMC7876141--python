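import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svgex.breakpoint_matrices import WindowSpec, BreakpointPresenceMatrix
from svgex.io_formats import GeneAnnotation, IntervalSet, SSVRecord
from svgex.regulatory_context import (
    TADClass,
    TADIndex,
    classify_tad,
    classify_tads,
    cna_ssv_enrichment,
    detect_enhancer_translocation,
    scan_enhancer_translocations,
    tad_enrichment,
)
from svgex.synthetic_cohort import CohortParams, _random_ssv

from conftest import make_ssv


TADS = IntervalSet(
    "tads",
    [
        ("chr1", 0, 1_000_000),
        ("chr1", 1_000_000, 2_000_000),
        ("chr1", 2_500_000, 3_000_000),  # gap 2,000,000-2,500,000
        ("chr2", 0, 1_000_000),
    ],
)


class TestClassifyTad:
    def test_same_tad_preserving(self):
        s = make_ssv(pos1=100, pos2=900_000)
        assert classify_tad(s, TADS).tad_class == "preserving"

    def test_interchromosomal_disrupting(self):
        s = SSVRecord("S", "translocation", "chr1", 500, "positive",
                      "chr2", 500, "negative", "T1")
        assert classify_tad(s, TADS).tad_class == "disrupting"

    def test_different_tads_disrupting(self):
        s = make_ssv(pos1=900_000, pos2=1_100_000)
        assert classify_tad(s, TADS).tad_class == "disrupting"

    def test_breakend_in_gap_unresolved(self):
        s = make_ssv(pos1=500_000, pos2=2_200_000)
        assert classify_tad(s, TADS).tad_class == "unresolved"

    def test_overlapping_tads_rejected(self):
        bad = IntervalSet("bad", [("chr1", 0, 100), ("chr1", 50, 200)])
        with pytest.raises(ValueError, match="overlap"):
            classify_tad(make_ssv(pos1=10, pos2=20), bad)

    def test_boundary_is_half_open(self):
        # breakend at exactly 1,000,000 belongs to the second TAD
        s = make_ssv(pos1=999_999, pos2=1_000_000)
        assert classify_tad(s, TADS).tad_class == "disrupting"


def brute_force_tad_class(ssv, intervals):
    def containing(chrom, pos):
        hits = [
            (c, s, e) for (c, s, e) in intervals if c == chrom and s <= pos < e
        ]
        return hits[0] if hits else None

    t1 = containing(ssv.chrom1, ssv.pos1)
    t2 = containing(ssv.chrom2, ssv.pos2)
    if t1 is None or t2 is None:
        return "unresolved"
    return "preserving" if t1 == t2 else "disrupting"


def test_classify_matches_brute_force_oracle():
    params = CohortParams(seed=3, n_chromosomes=4, chrom_length=10_000_000, n_genes=10)
    rng = np.random.default_rng(9)
    tads = IntervalSet(
        "t",
        [
            (f"chr{c}", s, s + 400_000)
            for c in range(1, 5)
            for s in range(0, 9_500_000, 500_000)
        ],
    )
    classes = ["deletion", "duplication", "inversion", "insertion", "translocation"]
    index = TADIndex(tads)
    for k in range(1000):
        svclass = classes[int(rng.integers(0, len(classes)))]
        s = _random_ssv(f"S{k}", "T1", svclass, params, rng)
        got = classify_tad(s, index).tad_class
        assert got == brute_force_tad_class(s, tads.intervals)
        if s.chrom1 != s.chrom2:
            assert got != "preserving"


class TestTadEnrichment:
    def _classes(self, n_disrupt, n_total, prefix):
        out = [TADClass(f"{prefix}{i}", "disrupting") for i in range(n_disrupt)]
        out += [TADClass(f"{prefix}{i}", "preserving") for i in range(n_disrupt, n_total)]
        return out

    def test_strong_enrichment(self):
        background = self._classes(100, 200, "b")
        altered = self._classes(90, 100, "a")
        result = tad_enrichment(background + altered, {c.ssv_id for c in altered})
        assert result["p_value"] < 1e-6
        # oracle: same table through the generic chi-squared routine
        table = np.array([[90, 10], [190, 110]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert np.isclose(result["p_value"], p)
        assert np.isclose(result["chi2"], chi2)

    def test_identical_fractions_not_significant(self):
        background = self._classes(50, 100, "b")
        altered = self._classes(25, 50, "a")
        result = tad_enrichment(background + altered, {c.ssv_id for c in altered})
        assert result["p_value"] > 0.5

    def test_empty_altered_set_rejected(self):
        with pytest.raises(ValueError):
            tad_enrichment(self._classes(5, 10, "b"), set())

    def test_unresolved_excluded(self):
        classes = self._classes(5, 10, "b") + [TADClass("u1", "unresolved")]
        result = tad_enrichment(classes, {"b0", "b1"})
        assert result["all_total"] == 10


# ---------------------------------------------------------------------------
# Enhancer-translocation enumeration grid.
#
# Geometry: gene TSS at 2,000,000 on chr1; proximal breakend 100 kb
# upstream (strand-dependent side); mate at 50,000,000 on chr9 with
# 'negative' orientation, so its retained side runs rightward.  Expected
# outcomes derived once by hand from the orientation rule:
#   call <=> orientation matches strand AND a fused-side enhancer lies
#            within 500 kb of the mate AND the native enhancer is absent
#            within 1 Mb or farther (from the TSS) than the fused one is
#            (from the mate breakend).
# ---------------------------------------------------------------------------

STRANDS = ("+", "-")
ORIENTS = ("positive", "negative")
FUSED = ("near", "far", "absent")     # 200 kb / 700 kb / none, rightward of mate
NATIVE = ("near", "far", "absent")    # 100 kb / 800 kb / none, from the TSS

EXPECTED = {
    (strand, orient, fused, native): (
        ((strand == "+" and orient == "negative") or (strand == "-" and orient == "positive"))
        and fused == "near"
        and native != "near"
    )
    for strand, orient, fused, native in itertools.product(STRANDS, ORIENTS, FUSED, NATIVE)
}


def _grid_case(strand, orient, fused, native):
    tss = 2_000_000
    if strand == "+":
        gene = GeneAnnotation("G", "chr1", tss, tss + 50_000, "+")
        prox = tss - 100_000
    else:
        gene = GeneAnnotation("G", "chr1", tss - 50_000 + 1, tss + 1, "-")
        prox = tss + 100_000
    mate_pos = 50_000_000
    ssv = SSVRecord(
        "S", "translocation", "chr1", prox, orient, "chr9", mate_pos, "negative", "T1"
    )
    intervals = []
    if fused == "near":
        intervals.append(("chr9", mate_pos + 200_000 - 500, mate_pos + 200_000 + 500))
    elif fused == "far":
        intervals.append(("chr9", mate_pos + 700_000 - 500, mate_pos + 700_000 + 500))
    if native == "near":
        intervals.append(("chr1", tss - 100_000 - 500 - 3_000, tss - 100_000 + 500 - 3_000))
    elif native == "far":
        intervals.append(("chr1", tss + 800_000 - 500, tss + 800_000 + 500))
    return ssv, gene, IntervalSet("enh", intervals)


@pytest.mark.parametrize(
    "strand,orient,fused,native",
    sorted(EXPECTED),
    ids=lambda v: str(v),
)
def test_enhancer_grid_cell(strand, orient, fused, native):
    ssv, gene, enhancers = _grid_case(strand, orient, fused, native)
    call = detect_enhancer_translocation(ssv, gene, enhancers)
    assert (call is not None) == EXPECTED[(strand, orient, fused, native)]
    if call is not None:
        assert call.distance_to_breakend == 200_000
        assert call.distance_to_breakend <= 500_000
        if native == "far":
            assert call.native_enhancer_distance == pytest.approx(800_000, abs=1_000)
        else:
            assert call.native_enhancer_distance is None


def test_native_enhancer_closer_blocks_call():
    ssv, gene, _ = _grid_case("+", "negative", "near", "absent")
    tss = gene.tss
    enhancers = IntervalSet(
        "enh",
        [
            ("chr9", 50_000_000 + 200_000 - 500, 50_000_000 + 200_000 + 500),
            ("chr1", tss - 50_000 - 500, tss - 50_000 + 500),  # native at 50 kb
        ],
    )
    assert detect_enhancer_translocation(ssv, gene, enhancers) is None


def test_scan_uses_closest_breakend_and_dedups():
    ssv, gene, enhancers = _grid_case("+", "negative", "near", "absent")
    # second SSV with a qualifying breakend closer to the TSS but wrong mate side
    closer = SSVRecord(
        "S2", "translocation", "chr1", gene.tss - 10_000, "negative",
        "chr9", 70_000_000, "positive", "T1",
    )
    calls = scan_enhancer_translocations([ssv, closer], [gene], enhancers)
    # the closest qualifying breakend (S2) wins, and its fused side has no
    # enhancer leftward of 70 Mb -> no call survives
    assert calls == []
    calls = scan_enhancer_translocations([ssv], [gene], enhancers)
    assert len(calls) == 1 and calls[0].ssv_id == "S"


class TestCnaSsvEnrichment:
    def _presence(self, values, genes, tumors):
        return BreakpointPresenceMatrix(
            pd.DataFrame(values, index=genes, columns=tumors),
            WindowSpec("symmetric", 1_000_000),
        )

    def test_planted_coupling_significant(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i}" for i in range(50)]
        tumors = [f"T{j}" for j in range(40)]
        coupled = rng.random((50, 40)) < 0.15
        presence = (rng.random((50, 40)) < 0.1) | coupled
        cna = np.where(coupled, 2, 0)
        result = cna_ssv_enrichment(
            self._presence(presence.astype(int), genes, tumors),
            pd.DataFrame(cna, index=genes, columns=tumors),
            level=2,
        )
        assert result["p_value"] < 1e-10
        assert result["n_both"] == int((presence & (cna == 2)).sum())

    def test_all_zero_cna_warns_p_one(self):
        genes, tumors = ["G1"], ["T1", "T2"]
        presence = self._presence([[1, 0]], genes, tumors)
        cna = pd.DataFrame(0, index=genes, columns=tumors)
        with pytest.warns(UserWarning):
            result = cna_ssv_enrichment(presence, cna, level=2)
        assert result["p_value"] == 1.0

    def test_independent_matrices_uniform_p(self):
        rng = np.random.default_rng(8)
        pvals = []
        genes = [f"G{i}" for i in range(40)]
        tumors = [f"T{j}" for j in range(30)]
        for _ in range(40):
            presence = (rng.random((40, 30)) < 0.3).astype(int)
            cna = np.where(rng.random((40, 30)) < 0.2, 2, 0)
            result = cna_ssv_enrichment(
                self._presence(presence, genes, tumors),
                pd.DataFrame(cna, index=genes, columns=tumors),
                level=2,
            )
            pvals.append(result["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            cna_ssv_enrichment(
                self._presence([[0]], ["G1"], ["T1"]),
                pd.DataFrame(0, index=["G1"], columns=["T1"]),
                level=1,
            )
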