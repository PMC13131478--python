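"""Coverage storage, density queries, scaling and metagene matrices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from outronscan.coverage_engine import (
    CoverageError,
    CoverageTrack,
    cpm_scale,
    mean_density,
    metagene_reference_point,
    metagene_scaled,
    read_bedgraph,
    write_bedgraph,
)
from outronscan.genome_model import GenomicInterval

from conftest import array_track, constant_track


def _bedgraph(tmp_path, text, name="t.bedgraph"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestBedgraphIO:
    def test_single_record_dense_expansion(self, tmp_path):
        track = read_bedgraph(_bedgraph(tmp_path, "chrI\t0\t10\t2.0\n"))
        assert track.mean(GenomicInterval("chrI", 0, 10)) == 2.0

    def test_empty_file_is_all_zero(self, tmp_path):
        track = read_bedgraph(_bedgraph(tmp_path, ""))
        assert track.mean(GenomicInterval("chrI", 0, 100)) == 0.0

    def test_overlapping_records_rejected(self, tmp_path):
        text = "chrI\t0\t5\t1\nchrI\t3\t8\t1\n"
        with pytest.raises(CoverageError, match="overlap"):
            read_bedgraph(_bedgraph(tmp_path, text))

    def test_negative_value_rejected(self, tmp_path):
        with pytest.raises(CoverageError, match="negative"):
            read_bedgraph(_bedgraph(tmp_path, "chrI\t0\t5\t-1\n"))

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=120))
    def test_round_trip_conserves_total_signal(self, values):
        import tempfile
        from pathlib import Path

        track = array_track(values, chrom="chrI")
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "rt.bedgraph"
            write_bedgraph(track, path)
            again = read_bedgraph(path)
        total = again.values.get("chrI", np.zeros(1)).sum()
        assert total == pytest.approx(float(np.sum(values)))


class TestMeanDensity:
    def test_matches_per_base_hand_sum(self):
        rng = np.random.default_rng(5)
        values = rng.poisson(3.0, size=200).astype(float)
        track = array_track(values)
        iv = GenomicInterval("chrT", 0, 200)
        hand = sum(float(values[i]) for i in range(200)) / 200.0
        assert mean_density(track, iv) == pytest.approx(hand, abs=1e-12)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(6)
        values = rng.random(300)
        iv = GenomicInterval("chrT", 40, 260)
        d1 = mean_density(array_track(values), iv)
        d2 = mean_density(array_track(values * 3.5), iv)
        assert d2 == pytest.approx(3.5 * d1, rel=1e-12)

    def test_off_contig_bases_count_as_zero(self):
        track = array_track([1.0] * 100)
        assert mean_density(track, GenomicInterval("chrT", 50, 150)) == 0.5

    def test_zero_length_interval_rejected(self):
        track = constant_track(1.0)
        with pytest.raises(ValueError):
            GenomicInterval("chrT", 10, 10)
        with pytest.raises(CoverageError):
            track.fetch("chrT", 10, 10)


class TestCpmScale:
    def test_library_of_one_million_is_identity(self):
        track = constant_track(2.0)
        track.library_size = 1e6
        assert cpm_scale(track).values["chrT"][0] == 2.0

    def test_scaling_halves_at_double_library(self):
        track = constant_track(2.0)
        track.library_size = 2e6
        assert cpm_scale(track).values["chrT"][0] == 1.0

    def test_double_scaling_rejected(self):
        track = constant_track(1.0)
        track.library_size = 1e6
        with pytest.raises(CoverageError):
            cpm_scale(cpm_scale(track))

    def test_missing_library_size_rejected(self):
        with pytest.raises(CoverageError):
            cpm_scale(constant_track(1.0))


def brute_force_scaled_row(values, flank, body_len, bin_size, body=1000):
    """Independent oracle: per-base fractional binning of one 5'->3' row."""
    n_flank = flank // bin_size
    n_body = body // bin_size
    out = []
    for k in range(n_flank):
        out.append(np.mean(values[k * bin_size : (k + 1) * bin_size]))
    body = values[flank : flank + body_len]
    if body_len < bin_size:
        out.extend([body.mean()] * n_body)
    else:
        edges = np.linspace(0, body_len, n_body + 1)
        for k in range(n_body):
            a, b = edges[k], edges[k + 1]
            acc = 0.0
            for i in range(int(np.floor(a)), min(int(np.ceil(b)), body_len)):
                weight = min(i + 1, b) - max(i, a)
                if weight > 0:
                    acc += weight * body[i]
            out.append(acc / (b - a))
    tail = values[flank + body_len :]
    for k in range(n_flank):
        out.append(np.mean(tail[k * bin_size : (k + 1) * bin_size]))
    return np.asarray(out)


class TestMetageneScaled:
    def test_constant_track_gives_constant_matrix(self):
        track = constant_track(3.25, length=20000)
        regions = [("r1", GenomicInterval("chrT", 5000, 7000, "+")),
                   ("r2", GenomicInterval("chrT", 9000, 9500, "-"))]
        mat = metagene_scaled(track, regions)
        assert mat.matrix.shape == (2, 300)
        assert np.all(mat.matrix == 3.25)

    def test_unlisted_contig_is_all_zero(self):
        track = constant_track(3.0)
        mat = metagene_scaled(track, [("r", GenomicInterval("chrX", 5000, 6000, "+"))])
        assert np.all(mat.matrix == 0.0)

    def test_step_body_rescales_to_halves(self):
        values = np.zeros(10000)
        values[5000:6000] = 0.0
        values[6000:7000] = 2.0
        track = array_track(values)
        mat = metagene_scaled(track, [("r", GenomicInterval("chrT", 5000, 7000, "+"))])
        body = mat.matrix[0, 100:200]
        assert np.allclose(body[:50], 0.0)
        assert np.allclose(body[50:], 2.0)

    def test_matches_brute_force_oracle_on_random_regions(self):
        rng = np.random.default_rng(9)
        values = rng.poisson(4.0, size=60000).astype(float)
        track = array_track(values)
        for _ in range(25):
            start = int(rng.integers(2000, 40000))
            length = int(rng.integers(5, 6000))
            region = GenomicInterval("chrT", start, start + length, "+")
            mat = metagene_scaled(track, [("r", region)])
            expected = brute_force_scaled_row(
                values[start - 1000 : start + length + 1000], 1000, length, 10
            )
            np.testing.assert_allclose(mat.matrix[0], expected, atol=1e-9)

    def test_strand_flip_symmetry(self):
        rng = np.random.default_rng(11)
        values = rng.poisson(2.0, size=20000).astype(float)
        plus = metagene_scaled(
            array_track(values), [("r", GenomicInterval("chrT", 6000, 8000, "+"))]
        )
        minus = metagene_scaled(
            array_track(values[::-1]),
            [("r", GenomicInterval("chrT", 20000 - 8000, 20000 - 6000, "-"))],
        )
        np.testing.assert_array_equal(plus.matrix, minus.matrix)

    def test_region_shorter_than_bin_uses_whole_region_mean(self):
        values = np.zeros(10000)
        values[5000:5005] = 10.0
        mat = metagene_scaled(array_track(values), [("r", GenomicInterval("chrT", 5000, 5005, "+"))])
        assert np.allclose(mat.matrix[0, 100:200], 10.0)


class TestMetageneReferencePoint:
    def test_point_at_contig_start_pads_with_zero(self):
        track = constant_track(1.0, length=10000)
        mat = metagene_reference_point(track, [("p", "chrT", 100, "+")], window=400)
        assert np.all(mat.matrix[0, :30] == 0.0)  # bases before 0
        assert np.all(mat.matrix[0, 40:] == 1.0)

    def test_step_function_splits_at_point(self):
        values = np.concatenate([np.full(5000, 2.0), np.full(5000, 7.0)])
        mat = metagene_reference_point(array_track(values), [("p", "chrT", 5000, "+")])
        assert np.all(mat.matrix[0, :40] == 2.0)
        assert np.all(mat.matrix[0, 40:] == 7.0)

    def test_minus_strand_row_is_flipped(self):
        values = np.concatenate([np.full(5000, 2.0), np.full(5000, 7.0)])
        mat = metagene_reference_point(array_track(values), [("p", "chrT", 5000, "-")])
        # 5' of a minus-strand point lies at higher coordinates
        assert np.all(mat.matrix[0, :40] == 7.0)
        assert np.all(mat.matrix[0, 40:] == 2.0)

    def test_antisense_selects_opposite_strand_track(self):
        tracks = {"+": constant_track(1.0), "-": constant_track(9.0)}
        sense = metagene_reference_point(tracks, [("p", "chrT", 5000, "+")])
        anti = metagene_reference_point(tracks, [("p", "chrT", 5000, "+")], antisense=True)
        assert np.all(sense.matrix == 1.0)
        assert np.all(anti.matrix == 9.0)
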