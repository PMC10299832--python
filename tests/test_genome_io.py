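"""Readers, writers, map interpolation and the Haldane map function."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkedsel import genome_io as gio


MAP_TEXT = (
    "chrom\tpos\trate_cM_Mb\tcm\n"
    "chr1\t0\t1.0\t0.0\n"
    "chr1\t1000000\t2.0\t1.0\n"
    "chr1\t2000000\t2.0\t3.0\n"
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGeneticMap:
    def test_parse_toy_map(self, tmp_path):
        gmap = gio.read_genetic_map(_write(tmp_path, "m.tsv", MAP_TEXT))
        assert len(gmap.table) == 3
        assert gmap.chroms == ["chr1"]

    def test_non_monotone_cm_rejected(self, tmp_path):
        bad = MAP_TEXT.replace("\t3.0\n", "\t0.5\n")
        with pytest.raises(gio.GenomeIOError, match="non-monotone"):
            gio.read_genetic_map(_write(tmp_path, "m.tsv", bad))

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(gio.GenomeIOError, match="empty"):
            gio.read_genetic_map(_write(tmp_path, "m.tsv", ""))

    def test_single_point_rejected(self, tmp_path):
        one = "chrom\tpos\trate_cM_Mb\tcm\nchr1\t5\t1.0\t0.0\n"
        with pytest.raises(gio.GenomeIOError, match="at least 2"):
            gio.read_genetic_map(_write(tmp_path, "m.tsv", one))

    def test_interpolation_values(self, toy_map):
        assert toy_map.interpolate("chr1", 500_000) == pytest.approx(0.5)
        # linear between (1e6, 1 cM) and (2e6, 3 cM)
        assert toy_map.interpolate("chr1", 1_500_000) == pytest.approx(2.0)
        assert toy_map.interpolate("chr1", 2_000_000) == pytest.approx(3.0)

    def test_out_of_range(self, toy_map):
        with pytest.raises(gio.GenomeIOError, match="outside mapped range"):
            toy_map.interpolate("chr1", 3_000_000)
        assert toy_map.interpolate("chr1", 3_000_000, clamp=True) == pytest.approx(3.0)
        with pytest.raises(gio.GenomeIOError, match="unknown chromosome"):
            toy_map.interpolate("chr9", 100)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 2_000_000), min_size=2, max_size=20))
    def test_interpolation_monotone(self, positions):
        gmap = gio.GeneticMap(
            pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": [0, 1_000_000, 2_000_000],
                    "rate": [1.0, 2.0, 2.0],
                    "cm": [0.0, 1.0, 3.0],
                }
            )
        )
        pos = np.sort(np.asarray(positions))
        cm = np.asarray(gmap.interpolate("chr1", pos))
        assert np.all(np.diff(cm) >= 0)

    def test_roundtrip(self, toy_map, tmp_path):
        gio.write_genetic_map(toy_map, tmp_path / "m.tsv")
        back = gio.read_genetic_map(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.table, toy_map.table)


class TestHaldane:
    def test_values(self):
        assert gio.cm_to_recfrac(0.0) == 0.0
        assert gio.cm_to_recfrac(1.0) == pytest.approx(0.0099007, abs=1e-6)
        assert gio.cm_to_recfrac(1e9) == pytest.approx(0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            gio.cm_to_recfrac(-0.1)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(1e-6, 500.0), st.floats(1e-6, 500.0))
    def test_monotone_and_bounded(self, d1, d2):
        r1, r2 = gio.cm_to_recfrac(d1), gio.cm_to_recfrac(d2)
        assert 0 < r1 < 0.5
        if d1 < d2:
            assert r1 <= r2

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1e-9, 0.1))
    def test_small_distance_linear(self, d):
        # r ~ d/100 (Morgans) with relative error < 1e-3 for d <= 0.1 cM
        assert gio.cm_to_recfrac(d) == pytest.approx(d / 100.0, rel=1e-3)


class TestIntervalFormats:
    def test_bed_roundtrip(self, tmp_path):
        ann = gio.AnnotationSet(
            class_label="conserved",
            intervals=pd.DataFrame(
                {"chrom": "chr1", "start": [10, 100], "end": [20, 250]}
            ),
        )
        gio.write_bed(ann, tmp_path / "a.bed")
        back = gio.read_bed(tmp_path / "a.bed", class_label="conserved")
        pd.testing.assert_frame_equal(back.intervals, ann.intervals)
        assert back.n_sites == 160

    def test_site_positions(self):
        ann = gio.AnnotationSet(
            class_label="x",
            intervals=pd.DataFrame({"chrom": "chr1", "start": [5], "end": [8]}),
        )
        # 0-based half-open [5, 8) -> 1-based sites 6, 7, 8
        assert list(ann.site_positions("chr1")) == [6, 7, 8]

    def test_mask_contains(self):
        mask = gio.NeutralMask(
            intervals=pd.DataFrame({"chrom": "chr1", "start": [0, 10], "end": [5, 12]})
        )
        got = mask.contains("chr1", np.array([1, 5, 6, 11, 12, 13]))
        assert list(got) == [True, True, False, True, True, False]

    @pytest.mark.parametrize(
        "rows",
        [
            [(10, 5)],            # end <= start
            [(10, 20), (15, 30)],  # overlap
            [(-5, 10)],           # negative start
        ],
    )
    def test_bad_intervals_rejected(self, rows):
        df = pd.DataFrame(rows, columns=["start", "end"])
        df.insert(0, "chrom", "chr1")
        with pytest.raises(gio.GenomeIOError):
            gio.NeutralMask(intervals=df)


class TestPolymorphism:
    def test_derived_counts(self, tmp_path):
        text = "chrom\tpos\tn\tk\nchr1\t10\t216\t1\n"
        table = gio.read_polymorphism(_write(tmp_path, "p.tsv", text))
        row = table.sites.iloc[0]
        assert row["C"] == 23220  # 216*215/2
        assert row["h"] == 215    # 1*(216-1)
        assert table.h[0] <= table.C[0]

    def test_h_column_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": "chr1", "pos": [1, 5], "n": 216, "k": [0, 1], "h": [23, 310]}
        )
        table = gio.PolymorphismTable(sites=df)
        gio.write_polymorphism(table, tmp_path / "p.tsv")
        back = gio.read_polymorphism(tmp_path / "p.tsv")
        assert list(back.h) == [23, 310]

    @pytest.mark.parametrize(
        "n,k,h",
        [(1, 0, 0), (216, 217, 0), (216, 0, 30000)],
    )
    def test_invalid_rejected(self, n, k, h):
        df = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "n": [n], "k": [k], "h": [h]})
        with pytest.raises(gio.GenomeIOError):
            gio.PolymorphismTable(sites=df)


class TestMutationBlocks:
    def test_roundtrip_and_rates(self, tmp_path):
        blocks = gio.MutationRateBlocks(
            blocks=pd.DataFrame(
                {"chrom": "chr1", "start": [0, 100], "end": [100, 200], "m": [0.8, 1.2]}
            )
        )
        gio.write_mutation_blocks(blocks, tmp_path / "b.tsv")
        back = gio.read_mutation_blocks(tmp_path / "b.tsv")
        m = back.rates_for_sites(np.array(["chr1", "chr1"]), np.array([50, 150]))
        assert list(m) == [0.8, 1.2]
        # equal site weights -> mean exactly 1 passes the check
        back.rates_for_sites(
            np.array(["chr1", "chr1"]), np.array([50, 150]), check_mean=True
        )

    def test_uncovered_site_rejected(self):
        blocks = gio.MutationRateBlocks(
            blocks=pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [100], "m": [1.0]}
            )
        )
        with pytest.raises(gio.GenomeIOError, match="not covered"):
            blocks.rates_for_sites(np.array(["chr1"]), np.array([500]))

    def test_nonpositive_m_rejected(self):
        with pytest.raises(gio.GenomeIOError):
            gio.MutationRateBlocks(
                blocks=pd.DataFrame(
                    {"chrom": ["chr1"], "start": [0], "end": [10], "m": [0.0]}
                )
            )


class TestBMap:
    def _track(self, values):
        n = len(values)
        return gio.BMapTrack(
            intervals=pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": np.arange(n) * 10,
                    "end": (np.arange(n) + 1) * 10,
                    "value": values,
                }
            )
        )

    def test_scaled_write(self, tmp_path):
        gio.write_bmap(self._track([1.0, 0.8371]), tmp_path / "b.tsv", scale=1000)
        lines = (tmp_path / "b.tsv").read_text().strip().splitlines()
        assert lines[2].split("\t")[3] == "1000"
        assert lines[3].split("\t")[3] == "837"
        back = gio.read_bmap(tmp_path / "b.tsv")
        assert np.allclose(back.intervals["value"], [1.0, 0.8371], atol=0.5e-3)

    def test_unscaled_roundtrip_identity(self, tmp_path):
        vals = [0.123456, 0.999999, 0.0]
        gio.write_bmap(self._track(vals), tmp_path / "b.tsv", scale=None)
        back = gio.read_bmap(tmp_path / "b.tsv")
        assert np.allclose(back.intervals["value"], vals, atol=1e-12)

    def test_value_at(self):
        track = self._track([0.5, 0.9])
        got = track.value_at(np.array(["chr1", "chr1", "chr1"]), np.array([5, 15, 25]))
        assert got[0] == 0.5 and got[1] == 0.9 and np.isnan(got[2])

    def test_out_of_unit_rejected(self):
        with pytest.raises(gio.GenomeIOError):
            self._track([1.2])


class TestCorruptionFuzz:
    """Writers' outputs must be rejected after single-field corruption."""

    @pytest.mark.parametrize(
        "line_idx,field_idx,value",
        [
            (2, 3, "-1.0"),   # cm decreasing at row 2
            (2, 1, "0"),      # pos non-monotone
            (1, 2, "-3.0"),   # negative rate
        ],
    )
    def test_map_corruption(self, tmp_path, line_idx, field_idx, value):
        lines = MAP_TEXT.strip().splitlines()
        fields = lines[line_idx].split("\t")
        fields[field_idx] = value
        lines[line_idx] = "\t".join(fields)
        with pytest.raises(gio.GenomeIOError):
            gio.read_genetic_map(_write(tmp_path, "m.tsv", "\n".join(lines) + "\n"))

    def test_poly_corruption(self, tmp_path):
        text = "chrom\tpos\tn\tk\th\nchr1\t10\t216\t1\t215\n"
        bad = text.replace("\t215\n", "\t99999\n")  # h > C
        with pytest.raises(gio.GenomeIOError):
            gio.read_polymorphism(_write(tmp_path, "p.tsv", bad))
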