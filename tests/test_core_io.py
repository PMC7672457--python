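import numpy as np
import pandas as pd
import pytest

from crckit.core_io import (
    ExpressionMatrix,
    GenomicInterval,
    ParseError,
    Peak,
    PipelineConfig,
    PositionWeightMatrix,
    SignalTrack,
    config_from_yaml,
    read_bed,
    read_bedgraph,
    read_expression_tsv,
    read_fasta,
    read_meme_motifs,
    write_bed,
    write_bedgraph,
    write_expression_tsv,
    write_fasta,
    write_meme_motifs,
)


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))  # abutting
        assert a.overlaps(GenomicInterval("chr1", 9, 20))

    def test_distance(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.distance_to(150) == 0
        assert iv.distance_to(99) == 1
        assert iv.distance_to(199) == 0
        assert iv.distance_to(200) == 1


class TestBed:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("")
        assert read_bed(p) == []

    def test_single_record(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t100\tp1\t5\n")
        peaks = read_bed(p)
        assert peaks == [Peak(GenomicInterval("chr1", 0, 100), "p1", 5.0)]

    def test_sorted_against_oracle(self, tmp_path, rng):
        rows = []
        for i in range(100):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 10000))
            rows.append((chrom, start, start + int(rng.integers(1, 100)), f"p{i}"))
        p = tmp_path / "x.bed"
        p.write_text("".join(f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in rows))
        got = [(q.interval.chrom, q.interval.start, q.interval.end) for q in read_bed(p)]
        assert got == sorted((c, s, e) for c, s, e, _ in rows)

    @pytest.mark.parametrize(
        "line", ["chr1\t0\n", "chr1\tx\t10\n", "chr1\t10\t10\n", "chr1\t20\t10\n"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t5\n" + line)
        with pytest.raises(ParseError, match=":2"):
            read_bed(p)

    def test_autogenerated_names_and_roundtrip(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t100\n")
        peaks = read_bed(p)
        assert peaks[0].name == "peak_1" and peaks[0].signal == 0.0
        out = tmp_path / "y.bed"
        write_bed(peaks, out)
        assert read_bed(out) == peaks


class TestBedGraph:
    def test_single_segment(self, tmp_path):
        p = tmp_path / "x.bg"
        p.write_text("chr1\t0\t10\t2.5\n")
        track = read_bedgraph(p)
        assert track.region_sum("chr1", 0, 10) == pytest.approx(25.0)

    def test_overlap_is_error(self, tmp_path):
        p = tmp_path / "x.bg"
        p.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t1\n")
        with pytest.raises(ParseError, match="overlap"):
            read_bedgraph(p)

    def test_negative_value_is_error(self, tmp_path):
        p = tmp_path / "x.bg"
        p.write_text("chr1\t0\t10\t-1\n")
        with pytest.raises(ParseError):
            read_bedgraph(p)

    def test_roundtrip_random_segments(self, tmp_path, rng):
        records = []
        pos = 0
        for _ in range(50):
            pos += int(rng.integers(1, 50))
            end = pos + int(rng.integers(1, 30))
            records.append(("chr1", pos, end, float(np.round(rng.uniform(0, 9), 4))))
            pos = end
        track = SignalTrack.from_records(records)
        p = tmp_path / "x.bg"
        write_bedgraph(track, p)
        assert read_bedgraph(p) == track

    def test_values_at_uncovered_is_zero(self):
        track = SignalTrack.from_records([("chr1", 10, 20, 3.0)])
        np.testing.assert_allclose(
            track.values_at("chr1", np.array([5, 10, 19, 20])), [0, 3, 3, 0]
        )


class TestFasta:
    def test_uppercase_single(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">chr1\nacgt\n")
        assert read_fasta(p) == {"chr1": "ACGT"}

    def test_two_records(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">chr1 desc\nACGT\n>chr2\nNNNN\n")
        genome = read_fasta(p)
        assert set(genome) == {"chr1", "chr2"}

    def test_duplicate_header_error(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">chr1\nAC\n>chr1\nGT\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_fasta(p)

    def test_roundtrip_random_kb(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=1000))
        p = tmp_path / "x.fa"
        write_fasta({"chrZ": seq}, p)
        assert read_fasta(p) == {"chrZ": seq}


class TestMemeMotifs:
    def test_width_one_motif(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF M1\n"
            "letter-probability matrix: alength= 4 w= 1\n 1 0 0 0\n"
        )
        (m,) = read_meme_motifs(p)
        assert m.width == 1 and m.probs[0, 0] == 1.0

    def test_uniform_background_default(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\nMOTIF M1\nletter-probability matrix:\n 0.25 0.25 0.25 0.25\n"
        )
        (m,) = read_meme_motifs(p)
        np.testing.assert_allclose(m.background, [0.25] * 4)

    def test_row_sum_error(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\nMOTIF M1\nletter-probability matrix:\n 0.5 0.25 0.2 0\n"
        )
        with pytest.raises(ParseError, match="sums to"):
            read_meme_motifs(p)

    def test_width_mismatch_error(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(
            "MEME version 4\nMOTIF M1\n"
            "letter-probability matrix: alength= 4 w= 2\n 1 0 0 0\n"
        )
        with pytest.raises(ParseError, match="w=2"):
            read_meme_motifs(p)

    def test_roundtrip_random_motif(self, tmp_path, rng):
        m = PositionWeightMatrix("R1", rng.dirichlet(np.ones(4), size=8))
        p = tmp_path / "m.meme"
        write_meme_motifs([m], p)
        (back,) = read_meme_motifs(p)
        assert back.motif_id == "R1" and back.width == 8
        np.testing.assert_allclose(back.probs, m.probs, atol=2e-6)


class TestExpression:
    def _write(self, tmp_path, df, lineage_lines):
        e = tmp_path / "e.tsv"
        l = tmp_path / "l.tsv"
        df.to_csv(e, sep="\t", index_label="gene_id")
        l.write_text(lineage_lines)
        return e, l

    def test_small_matrix(self, tmp_path):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g1"])
        e, l = self._write(tmp_path, df, "s1\tA\ns2\tB\n")
        expr = read_expression_tsv(e, l)
        assert expr.genes == ["g1"] and expr.lineages == ["A", "B"]

    def test_unlabeled_sample_error(self, tmp_path):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g1"])
        e, l = self._write(tmp_path, df, "s1\tA\n")
        with pytest.raises(ValueError, match="lineage"):
            read_expression_tsv(e, l)

    def test_negative_tpm_error(self):
        df = pd.DataFrame({"s1": [-1.0]}, index=["g1"])
        with pytest.raises(ValueError):
            ExpressionMatrix(df, {"s1": "A"})

    def test_roundtrip_random(self, tmp_path, rng):
        df = pd.DataFrame(
            np.round(rng.uniform(0, 100, size=(20, 10)), 4),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(10)],
        )
        expr = ExpressionMatrix(df, {f"s{i}": f"L{i % 3}" for i in range(10)})
        e, l = tmp_path / "e.tsv", tmp_path / "l.tsv"
        write_expression_tsv(expr, e, l)
        back = read_expression_tsv(e, l)
        pd.testing.assert_frame_equal(back.values, expr.values)
        assert back.lineage == expr.lineage


class TestConfig:
    def test_empty_file_gives_defaults(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("")
        cfg = config_from_yaml(p)
        assert cfg == PipelineConfig()
        assert cfg.se_extension_bp == 500

    def test_bad_value_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("se_extension_bp: -1\n")
        with pytest.raises(ValueError, match="se_extension_bp"):
            config_from_yaml(p)

    def test_unknown_keys_all_named(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("nope: 1\nalso_nope: 2\n")
        with pytest.raises(ValueError, match="also_nope, nope"):
            config_from_yaml(p)
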