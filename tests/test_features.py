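"""Feature aggregation onto the bin grid and Spearman correlation summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polkmap import (BinnedTrack, aggregate_coverage_fraction, aggregate_signal_mean,
                     correlate_replicates, correlation_report,
                     gc_fraction_from_sequences, make_bins, replication_score,
                     spearman, spearman_null_band)


def brute_force_coverage(intervals, grid):
    """Per-base oracle: fraction of each bin's bases inside any interval."""
    out = np.zeros(grid.n_bins)
    for i in range(grid.n_bins):
        covered = 0
        for pos in range(grid.starts[i], grid.ends[i]):
            if any(c == grid.chroms[i] and s <= pos < e for c, s, e in intervals):
                covered += 1
        out[i] = covered / (grid.ends[i] - grid.starts[i])
    return out


@pytest.fixture
def kb_grid():
    """Two 1 kb bins on a 2 kb chromosome."""
    return make_bins({"chr1": 2_000}, 1_000)


class TestCoverageFraction:
    def test_half_bin(self, kb_grid):
        fv = aggregate_coverage_fraction([("chr1", 0, 500)], kb_grid)
        assert fv.values[0] == 0.5

    def test_union_not_sum(self, kb_grid):
        fv = aggregate_coverage_fraction(
            [("chr1", 0, 500), ("chr1", 0, 500)], kb_grid)
        assert fv.values[0] == 0.5

    def test_overlapping_intervals_vs_per_base_oracle(self, kb_grid):
        intervals = [("chr1", 0, 100), ("chr1", 50, 150)]
        fv = aggregate_coverage_fraction(intervals, kb_grid)
        assert fv.values[0] == pytest.approx(0.15)
        np.testing.assert_allclose(fv.values, brute_force_coverage(intervals, kb_grid))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_intervals_vs_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = make_bins({"c1": 300, "c2": 150}, 100)
        intervals = []
        for _ in range(rng.integers(1, 12)):
            chrom = rng.choice(["c1", "c2"])
            size = 300 if chrom == "c1" else 150
            s = int(rng.integers(0, size - 1))
            e = int(rng.integers(s + 1, size + 1))
            intervals.append((chrom, s, e))
        fv = aggregate_coverage_fraction(intervals, grid)
        np.testing.assert_allclose(fv.values, brute_force_coverage(intervals, grid))


class TestSignalMean:
    def test_constant_signal(self, kb_grid):
        fv = aggregate_signal_mean([("chr1", 0, 2_000, 2.0)], kb_grid)
        np.testing.assert_allclose(fv.values, [2.0, 2.0])

    def test_absent_signal_counts_as_zero(self, kb_grid):
        fv = aggregate_signal_mean([("chr1", 0, 500, 4.0)], kb_grid)
        assert fv.values[0] == pytest.approx(2.0)
        assert fv.values[1] == 0.0

    def test_empty_signal(self, kb_grid):
        fv = aggregate_signal_mean([], kb_grid)
        assert list(fv.values) == [0.0, 0.0]

    def test_overlapping_signal_rejected(self, kb_grid):
        with pytest.raises(ValueError, match="overlap"):
            aggregate_signal_mean(
                [("chr1", 0, 500, 1.0), ("chr1", 400, 900, 2.0)], kb_grid)

    def test_bp_weighted_mean_vs_per_base_oracle(self, kb_grid):
        steps = [("chr1", 100, 400, 3.0), ("chr1", 700, 1_200, -1.5)]
        fv = aggregate_signal_mean(steps, kb_grid)
        for i in range(kb_grid.n_bins):  # oracle: sum value over each base
            total = sum(v for _, s, e, v in steps
                        for pos in range(kb_grid.starts[i], kb_grid.ends[i])
                        if s <= pos < e)
            assert fv.values[i] == pytest.approx(total / 1_000)


class TestGCFraction:
    def test_known_strings(self):
        grid = make_bins({"chr1": 4}, 4)
        for seq, expected in [("GGCC", 1.0), ("ATGC", 0.5), ("ANGC", 2 / 3)]:
            fv = gc_fraction_from_sequences({"chr1": seq}, grid)
            assert fv.values[0] == pytest.approx(expected)

    def test_all_n_bin_is_masked(self):
        grid = make_bins({"chr1": 8}, 4)
        fv = gc_fraction_from_sequences({"chr1": "NNNNATGC"}, grid)
        assert not fv.mask[0] and fv.mask[1]
        assert fv.values[1] == 0.5

    def test_length_mismatch_rejected(self):
        grid = make_bins({"chr1": 10}, 5)
        with pytest.raises(ValueError, match="length"):
            gc_fraction_from_sequences({"chr1": "ATGC"}, grid)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_all_permutations_match_closed_form(self):
        """rho equals 1 − 6Σd²/(n(n²−1)) for every permutation of 4 distinct values."""
        x = np.array([10.0, 20.0, 30.0, 40.0])
        for perm in itertools.permutations(range(4)):
            y = x[list(perm)]
            d = np.arange(4) - np.array(perm)
            expected = 1 - 6 * np.sum(d**2) / (4 * (16 - 1))
            assert spearman(x, y) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=30, unique=True),
           st.integers(0, 3))
    def test_invariant_under_monotone_transform(self, values, which):
        rng = np.random.default_rng(hash(tuple(values)) % 2**31)
        x = np.asarray(values, dtype=float)
        y = rng.normal(size=x.size)
        transform = [np.exp, lambda v: v**3, lambda v: 5 * v + 2,
                     lambda v: np.arctan(v)][which]
        assert spearman(transform(x), y) == pytest.approx(spearman(x, y))

    def test_mask_restricts_bins(self):
        x = np.array([1.0, 2, 3, 100.0])
        y = np.array([1.0, 2, 3, -50.0])
        mask = np.array([True, True, True, False])
        assert spearman(x, y, mask) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="3"):
            spearman([1, 2], [1, 2])


class TestCorrelateReplicates:
    def _tracks(self, grid, arrays):
        return [BinnedTrack(grid, np.asarray(a, dtype=float), "log2_enrichment",
                            replicate_id=i + 1) for i, a in enumerate(arrays)]

    def test_identical_replicates_have_zero_sd(self, kb_grid):
        grid = make_bins({"chr1": 5_000}, 1_000)
        vals = [0.1, -0.5, 1.2, 0.0, 0.4]
        tracks = self._tracks(grid, [vals] * 6)
        from polkmap import FeatureVector
        fv = FeatureVector(grid, np.arange(5, dtype=float), "f", "signal_mean")
        s = correlate_replicates(tracks, fv)
        assert s.sd_rho == 0.0 and s.n_replicates == 6
        assert s.n_bins_used == 5

    def test_single_replicate_flagged(self):
        grid = make_bins({"chr1": 5_000}, 1_000)
        from polkmap import FeatureVector
        fv = FeatureVector(grid, np.arange(5, dtype=float), "f", "signal_mean")
        s = correlate_replicates(self._tracks(grid, [[1, 3, 2, 5, 4]]), fv)
        assert s.single_replicate and s.sd_rho == 0.0
        assert s.mean_rho == pytest.approx(s.per_replicate_rho[0])

    def test_mask_intersection_counts(self):
        grid = make_bins({"chr1": 5_000}, 1_000)
        from polkmap import FeatureVector
        t = BinnedTrack(grid, np.array([1.0, 2, 3, 4, 5]), "log2_enrichment",
                        mask=np.array([True, True, True, True, False]))
        fv = FeatureVector(grid, np.arange(5, dtype=float), "f", "signal_mean",
                           mask=np.array([False, True, True, True, True]))
        s = correlate_replicates([t], fv)
        assert s.n_bins_used == 3


class TestReplicationScore:
    def _raw(self, grid, vals):
        return BinnedTrack(grid, np.asarray(vals), "raw_count")

    def test_equal_libraries_give_zero(self, kb_grid):
        grid = make_bins({"chr1": 3_000}, 1_000)
        fv = replication_score(self._raw(grid, [5, 8, 2]), self._raw(grid, [5, 8, 2]))
        np.testing.assert_allclose(fv.values, 0.0)

    def test_fourfold_early_gives_two(self):
        grid = make_bins({"chr1": 2_000}, 1_000)
        # equal library totals, E = 4L in bin 0
        fv = replication_score(self._raw(grid, [8, 2]), self._raw(grid, [2, 8]),
                               pseudocount=0)
        assert fv.values[0] == pytest.approx(2.0)

    def test_depth_invariance(self):
        grid = make_bins({"chr1": 3_000}, 1_000)
        e, l = [6, 3, 1], [2, 5, 3]
        a = replication_score(self._raw(grid, e), self._raw(grid, l), 0.5)
        b = replication_score(self._raw(grid, e), self._raw(grid, [v * 2 for v in l]), 0.5)
        np.testing.assert_allclose(a.values, b.values)


class TestCorrelationReport:
    def _summary(self, name, rhos):
        from polkmap import CorrelationSummary
        rhos = tuple(rhos)
        sd = float(np.std(rhos, ddof=1)) if len(rhos) > 1 else 0.0
        return CorrelationSummary(name, rhos, float(np.mean(rhos)), sd, 100)

    def test_empty_input_gives_header_only(self, tmp_path):
        path = tmp_path / "report.tsv"
        df = correlation_report([], path)
        assert len(df) == 0
        assert path.read_text().startswith("feature\t")

    def test_sorted_by_abs_mean_rho(self):
        df = correlation_report([self._summary("weak", [-0.1, -0.1]),
                                 self._summary("strong", [0.4, 0.4])])
        assert list(df["feature"]) == ["strong", "weak"]

    def test_ties_broken_alphabetically(self):
        df = correlation_report([self._summary("zeta", [0.3]),
                                 self._summary("alpha", [-0.3])])
        assert list(df["feature"]) == ["alpha", "zeta"]


def test_null_band_shrinks_with_sample_size():
    wide = spearman_null_band(20, n_perm=500, seed=1)
    narrow = spearman_null_band(500, n_perm=500, seed=1)
    assert 0 < narrow < wide < 1
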