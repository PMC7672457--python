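import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crckit.core_io import GeneAnnotation, GenomicInterval, Peak, SignalTrack
from crckit.superenhancer import (
    assign_to_genes,
    call_super_enhancers,
    hockey_stick_cutoff,
    rank_by_signal,
    se_assigned_tfs,
    stitch_peaks,
)


def _peaks(spans, chrom="chr1"):
    return [
        Peak(GenomicInterval(chrom, s, e), f"p{i}") for i, (s, e) in enumerate(spans)
    ]


def _merge_oracle(spans, gap):
    """Brute-force transitive interval merge."""
    spans = sorted(spans)
    out = []
    for s, e in spans:
        if out and s - out[-1][1] <= gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


class TestStitch:
    def test_gap_larger_than_stitch(self):
        regions = stitch_peaks(_peaks([(0, 100), (200, 300)]), 50)
        assert len(regions) == 2

    def test_gap_within_stitch(self):
        (r,) = stitch_peaks(_peaks([(0, 100), (200, 300)]), 150)
        assert (r.interval.start, r.interval.end) == (0, 300)
        assert r.constituent_ids == ("p0", "p1")

    def test_tss_exclusion_drops_contained_peaks(self):
        # the promoter-proximal peak sits fully inside TSS +- 2500
        peaks = _peaks([(4000, 5000), (9000, 10000)])
        regions = stitch_peaks(peaks, 100, [("chr1", 4500)], 2500)
        assert len(regions) == 1
        assert regions[0].interval.start == 9000

    def test_matches_merge_oracle_random(self, rng):
        spans = []
        for _ in range(200):
            s = int(rng.integers(0, 100000))
            spans.append((s, s + int(rng.integers(1, 500))))
        # drop overlap duplicates to keep peak names unique but spans may overlap
        regions = stitch_peaks(_peaks(spans), 250)
        got = [(r.interval.start, r.interval.end) for r in regions]
        assert got == _merge_oracle(spans, 250)

    def test_idempotent_and_monotone(self, rng):
        spans = []
        for _ in range(100):
            s = int(rng.integers(0, 50000))
            spans.append((s, s + int(rng.integers(1, 400))))
        first = stitch_peaks(_peaks(spans), 300)
        again = stitch_peaks(
            [Peak(r.interval, f"r{i}") for i, r in enumerate(first)], 300
        )
        assert [r.interval for r in again] == [r.interval for r in first]
        counts = [len(stitch_peaks(_peaks(spans), g)) for g in (10, 100, 1000, 10000)]
        assert counts == sorted(counts, reverse=True)


class TestRankBySignal:
    def test_flat_track(self):
        regions = stitch_peaks(_peaks([(0, 100)]), 10)
        track = SignalTrack.from_records([("chr1", 0, 100, 2.0)])
        (se,) = rank_by_signal(regions, track)
        assert se.total_signal == pytest.approx(200.0)

    def test_control_cancels(self):
        regions = stitch_peaks(_peaks([(0, 100)]), 10)
        track = SignalTrack.from_records([("chr1", 0, 100, 2.0)])
        (se,) = rank_by_signal(regions, track, control=track)
        assert se.total_signal == 0.0

    def test_per_base_oracle(self, rng):
        segs, pos = [], 0
        for _ in range(80):
            pos += int(rng.integers(1, 40))
            end = pos + int(rng.integers(1, 40))
            segs.append(("chr1", pos, end, float(rng.uniform(0, 5))))
            pos = end
        track = SignalTrack.from_records(segs)
        ctrl_segs = [("chr1", s, e, float(rng.uniform(0, 3))) for _, s, e, _ in segs[::2]]
        control = SignalTrack.from_records(ctrl_segs)
        spans = []
        for _ in range(50):
            s = int(rng.integers(0, 2500))
            spans.append((s, s + int(rng.integers(10, 300))))
        regions = stitch_peaks(_peaks(spans), 1)
        got = rank_by_signal(regions, track, control)
        for se in got:
            iv = se.interval
            bases = np.arange(iv.start, iv.end)
            expected = np.maximum(
                track.values_at("chr1", bases) - control.values_at("chr1", bases), 0
            ).sum()
            assert se.total_signal == pytest.approx(expected, abs=1e-9)

    def test_rank_ties_broken_by_position(self):
        regions = stitch_peaks(_peaks([(0, 100), (200, 300)]), 10)
        track = SignalTrack.from_records(
            [("chr1", 0, 100, 1.0), ("chr1", 200, 300, 1.0)]
        )
        ses = rank_by_signal(regions, track)
        assert [se.rank for se in ses] == [1, 2]


class TestHockeyStick:
    def test_flat_curve_has_no_supers(self):
        cutoff, n_super = hockey_stick_cutoff([1, 1, 1, 1])
        assert n_super == 0

    def test_worked_example(self):
        cutoff, n_super = hockey_stick_cutoff([1, 2, 3, 100])
        assert n_super == 1
        assert cutoff == 3

    def test_fewer_than_two_is_error(self):
        with pytest.raises(ValueError):
            hockey_stick_cutoff([5.0])

    def test_matches_exhaustive_argmax_oracle(self, rng):
        for _ in range(50):
            s = np.sort(rng.pareto(1.5, size=int(rng.integers(3, 40))) + 0.1)
            x = np.arange(len(s)) / (len(s) - 1)
            y = (s - s[0]) / (s[-1] - s[0])
            i_star = max(range(len(s)), key=lambda i: x[i] - y[i])
            cutoff, n_super = hockey_stick_cutoff(list(s))
            assert cutoff == pytest.approx(s[i_star])
            assert n_super == int((s > s[i_star]).sum())

    @given(
        st.lists(st.floats(0.1, 1e6), min_size=3, max_size=30),
        st.floats(0.1, 100),
        st.floats(0, 1000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance(self, signals, a, b):
        _, n1 = hockey_stick_cutoff(signals)
        _, n2 = hockey_stick_cutoff([a * s + b for s in signals])
        assert n1 == n2


class TestAssignment:
    GENES = [
        GeneAnnotation("tfA", "tfA", "chr1", "+", 500, True),
        GeneAnnotation("gB", "gB", "chr1", "+", 60000, False),
    ]

    def _ses(self, spans):
        regions = stitch_peaks(_peaks(spans), 1)
        track = SignalTrack.from_records(
            [(r.interval.chrom, r.interval.start, r.interval.end, 1.0)
             for r in regions]
        )
        return rank_by_signal(regions, track)

    def test_tss_inside_assigned(self):
        ses = assign_to_genes(self._ses([(0, 1000)]), self.GENES, 50000)
        assert "tfA" in ses[0].assigned_genes

    def test_boundary_window_plus_one(self):
        genes = [GeneAnnotation("g", "g", "chr1", "+", 1000 + 50000, False)]
        ses = assign_to_genes(self._ses([(0, 1000)]), genes, 50000)
        assert ses[0].assigned_genes == ()  # distance = window + 1
        genes2 = [GeneAnnotation("g", "g", "chr1", "+", 999 + 50000, False)]
        ses2 = assign_to_genes(self._ses([(0, 1000)]), genes2, 50000)
        assert ses2[0].assigned_genes == ("g",)

    def test_matches_all_pairs_oracle(self, rng):
        genes = [
            GeneAnnotation(f"g{i}", f"g{i}", "chr1", "+", int(rng.integers(0, 100000)), False)
            for i in range(30)
        ]
        spans = []
        for _ in range(15):
            s = int(rng.integers(0, 99000))
            spans.append((s, s + int(rng.integers(100, 1000))))
        ses = assign_to_genes(self._ses(spans), genes, 5000)
        for se in ses:
            expected = sorted(
                g.gene_id
                for g in genes
                if se.interval.distance_to(g.tss) <= 5000
            )
            assert sorted(se.assigned_genes) == expected

    def test_se_assigned_tfs(self, default_bundle, default_run):
        _, _, truth = default_bundle
        out_dir, manifest, _ = default_run
        import pandas as pd

        df = pd.read_csv(out_dir / "se_table.tsv", sep="\t")
        tf_rows = df[df.is_super == 1]
        found = set()
        for genes_str in tf_rows.assigned_genes.fillna(""):
            found |= set(g for g in genes_str.split(",") if g.startswith("TF"))
        expected = set(truth.se_assigned_tfs)
        assert {g for g in found if not g.startswith("TFX")} == expected
        assert manifest["counts"]["se_assigned_tfs"] == len(expected)

    def test_no_supers_gives_empty_tf_list(self):
        ses, _ = call_super_enhancers(self._ses([(0, 1000), (2000, 3000)]))
        ses = assign_to_genes(ses, self.GENES, 50000)
        assert se_assigned_tfs(ses, self.GENES) == []
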