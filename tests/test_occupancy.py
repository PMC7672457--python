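import numpy as np
import pandas as pd
import pytest

from crckit.core_io import (
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    SignalTrack,
)
from crckit.occupancy import (
    RegulatoryElement,
    assign_occupancy,
    classify_elements,
    expression_by_class,
    occupancy_fractions,
    se_overlap_by_class,
    signal_profile,
)
from crckit.superenhancer import SuperEnhancer, StitchedRegion


def _peak(chrom, s, e, name, signal=1.0):
    return Peak(GenomicInterval(chrom, s, e), name, signal)


def _gene(gid, chrom, tss):
    return GeneAnnotation(gid, gid, chrom, "+", tss, False)


class TestClassifyElements:
    def test_promoter_definition(self):
        elements, dropped = classify_elements(
            [_peak("chr1", 1000, 2000, "k27")],
            [_peak("chr1", 1200, 1600, "me3")],
            [],
            [_gene("g", "chr1", 1500)],
            promoter_window_bp=2000,
        )
        assert dropped == 0
        assert elements[0].element_class == "promoter"
        assert elements[0].assigned_gene == "g"

    def test_distal_enhancer_definition(self):
        elements, _ = classify_elements(
            [_peak("chr1", 100000, 101000, "k27")],
            [],
            [_peak("chr1", 100200, 100700, "me1")],
            [_gene("g", "chr1", 1500)],
        )
        assert elements[0].element_class == "enhancer"

    def test_both_marks_dropped(self):
        elements, dropped = classify_elements(
            [_peak("chr1", 1000, 2000, "k27")],
            [_peak("chr1", 1100, 1300, "me3")],
            [_peak("chr1", 1500, 1800, "me1")],
            [_gene("g", "chr1", 1500)],
        )
        assert elements == [] and dropped == 1

    def test_promoter_needs_tss_proximity(self):
        elements, dropped = classify_elements(
            [_peak("chr1", 100000, 101000, "k27")],
            [_peak("chr1", 100100, 100300, "me3")],
            [],
            [_gene("g", "chr1", 1500)],
            promoter_window_bp=2000,
        )
        assert elements == [] and dropped == 1

    def test_classes_disjoint_random_layout(self, rng):
        k27 = [
            _peak("chr1", int(s), int(s) + 500, f"k{i}")
            for i, s in enumerate(rng.integers(0, 50000, 40) * 1)
        ]
        me3 = [
            _peak("chr1", int(s), int(s) + 400, f"m3{i}")
            for i, s in enumerate(rng.integers(0, 50000, 20))
        ]
        me1 = [
            _peak("chr1", int(s), int(s) + 400, f"m1{i}")
            for i, s in enumerate(rng.integers(0, 50000, 20))
        ]
        genes = [_gene(f"g{i}", "chr1", int(t)) for i, t in enumerate(rng.integers(0, 50000, 10))]
        elements, dropped = classify_elements(k27, me3, me1, genes, 2000)
        assert len(elements) + dropped == len(k27)

        def overlaps_any(iv, peaks):
            return any(iv.overlaps(p.interval) for p in peaks)

        for el in elements:
            has3 = overlaps_any(el.interval, me3)
            has1 = overlaps_any(el.interval, me1)
            near = min(el.interval.distance_to(g.tss) for g in genes)
            if el.element_class == "promoter":
                assert has3 and not has1 and near <= 2000
            else:
                assert has1 and not has3


class TestAssignOccupancy:
    def _element(self, s, e):
        return RegulatoryElement(GenomicInterval("chr1", s, e), "promoter", "g")

    def test_no_peaks_all_zero(self):
        els = assign_occupancy([self._element(0, 100)], {"F1": [], "F2": []})
        assert els[0].occupancy == (False, False)

    def test_abutting_peak_does_not_overlap(self):
        els = assign_occupancy(
            [self._element(100, 200)],
            {"F1": [_peak("chr1", 200, 300, "p")], "F2": [_peak("chr1", 199, 300, "q")]},
        )
        assert els[0].occupancy == (False, True)

    def test_matches_overlap_oracle(self, rng):
        elements = [
            self._element(int(s), int(s) + 200)
            for s in rng.integers(0, 20000, 30)
        ]
        factors = {}
        for f in ("A", "B", "C"):
            factors[f] = [
                _peak("chr1", int(s), int(s) + 150, f"{f}{i}")
                for i, s in enumerate(rng.integers(0, 20000, 15))
            ]
        els = assign_occupancy(elements, factors)
        for el in els:
            expected = tuple(
                any(el.interval.overlaps(p.interval) for p in factors[f])
                for f in factors
            )
            assert el.occupancy == expected


class TestOccupancyFractions:
    def _elements(self, cls, n, bound):
        out = []
        for i in range(n):
            occ = (i < bound, False, False, False)
            out.append(
                RegulatoryElement(
                    GenomicInterval("chr1", 10 * i + 1, 10 * i + 5), cls, "g", occ
                )
            )
        return out

    def test_counts_sum_and_percent(self):
        els = self._elements("promoter", 100, 30)
        summary = occupancy_fractions(els, ["F1", "F2", "F3", "F4"])
        cls = summary.per_class["promoter"]
        assert cls["bound_percent"] == 30.0
        assert sum(cls["by_cardinality"].values()) == 100
        assert sum(cls["by_pattern"].values()) == 100

    def test_empty_error(self):
        with pytest.raises(ValueError):
            occupancy_fractions([], ["F"])

    def test_matches_counting_oracle(self, rng):
        factors = ["A", "B", "C", "D"]
        els = []
        for i in range(200):
            occ = tuple(bool(rng.integers(2)) for _ in factors)
            els.append(
                RegulatoryElement(
                    GenomicInterval("chr1", 10 * i + 1, 10 * i + 5),
                    "enhancer", "g", occ,
                )
            )
        s = occupancy_fractions(els, factors).per_class["enhancer"]
        bound = sum(any(e.occupancy) for e in els)
        assert s["bound"] == bound
        assert s["bound_percent"] == round(100 * bound / 200, 1)
        assert s["by_cardinality"].get("quad", 0) == sum(
            all(e.occupancy) for e in els
        )


class TestSignalProfile:
    def _el(self, center):
        return RegulatoryElement(
            GenomicInterval("chr1", center - 50, center + 50), "enhancer", "g"
        )

    def test_flat_track_constant_profile(self):
        track = SignalTrack.from_records([("chr1", 0, 100000, 3.0)])
        out = signal_profile({"g1": [self._el(5000)]}, track, 2000, 100)
        np.testing.assert_allclose(out["g1"], 3.0)

    def test_empty_group_warns_nan(self):
        track = SignalTrack.from_records([("chr1", 0, 1000, 1.0)])
        with pytest.warns(UserWarning):
            out = signal_profile({"none": []}, track, 2000, 100)
        assert np.isnan(out["none"]).all()

    def test_per_base_binning_oracle(self, rng):
        segs, pos = [], 0
        for _ in range(200):
            pos += int(rng.integers(1, 60))
            end = pos + int(rng.integers(1, 60))
            segs.append(("chr1", pos, end, float(rng.uniform(0, 5))))
            pos = end
        track = SignalTrack.from_records(segs)
        elements = [self._el(int(c)) for c in rng.integers(2100, 9000, 20)]
        out = signal_profile({"g": elements}, track, halfwidth_bp=2000, bins=40)
        acc = np.zeros(40)
        for el in elements:
            center = (el.interval.start + el.interval.end) // 2
            vals = track.values_at(
                "chr1", np.arange(center - 2000, center + 2000)
            )
            acc += vals.reshape(40, 100).mean(axis=1)
        np.testing.assert_allclose(out["g"], acc / 20, atol=1e-9)

    def test_invariant_to_element_order(self, rng):
        track = SignalTrack.from_records([("chr1", 0, 50000, 2.0)])
        els = [self._el(int(c)) for c in rng.integers(3000, 40000, 10)]
        a = signal_profile({"g": els}, track, 2000, 50)["g"]
        b = signal_profile({"g": els[::-1]}, track, 2000, 50)["g"]
        np.testing.assert_allclose(a, b)


class TestSeOverlap:
    def _groups(self):
        return {
            "in": [RegulatoryElement(GenomicInterval("chr1", 1000, 1200), "enhancer", "g")],
            "out": [RegulatoryElement(GenomicInterval("chr1", 90000, 90200), "enhancer", "g")],
        }

    def _se(self, s, e, is_super=True):
        region = StitchedRegion(GenomicInterval("chr1", s, e), ("p",), 100.0)
        return SuperEnhancer(region, rank=1, is_super=is_super)

    def test_no_supers_zero(self):
        out = se_overlap_by_class(self._groups(), [self._se(500, 2000, is_super=False)])
        assert out == {"in": 0.0, "out": 0.0}

    def test_group_inside_se(self):
        out = se_overlap_by_class(self._groups(), [self._se(500, 2000)])
        assert out == {"in": 1.0, "out": 0.0}


class TestExpressionByClass:
    def _expr(self):
        df = pd.DataFrame(
            {"s1": {"g0": 0.0, "g1": 10.0}, "s2": {"g0": 0.0, "g1": 10.0},
             "s3": {"g0": 0.0, "g1": 10.0}}
        )
        return ExpressionMatrix(df, {s: "A" for s in ("s1", "s2", "s3")})

    def _el(self, gene):
        return RegulatoryElement(GenomicInterval("chr1", 100, 200), "promoter", gene)

    def test_zero_tpm_maps_to_zero(self):
        values, _, _ = expression_by_class({"g": [self._el("g0")]}, self._expr())
        assert values["g"].tolist() == [0.0]

    def test_identical_groups_p_one(self):
        groups = {"a": [self._el("g1")], "b": [self._el("g1")]}
        _, _, pvals = expression_by_class(
            groups, self._expr(), test_pairs=[("a", "b")]
        )
        assert pvals[("a", "b")] == 1.0

    def test_values_match_lookup_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        df = pd.DataFrame(
            rng.uniform(0, 50, size=(12, 4)), index=genes,
            columns=["s1", "s2", "s3", "s4"],
        )
        expr = ExpressionMatrix(df, {s: "A" for s in df.columns})
        group = [self._el(g) for g in genes[:6]] + [self._el(genes[0])]
        values, quartiles, _ = expression_by_class({"g": group}, expr)
        expected = np.log2(df.loc[sorted(genes[:6])].mean(axis=1).to_numpy() + 1)
        np.testing.assert_allclose(sorted(values["g"]), sorted(expected))
        np.testing.assert_allclose(
            quartiles["g"], np.percentile(values["g"], [25, 50, 75])
        )
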