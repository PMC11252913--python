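"""Synthetic genome generation and the planted log-linear capture model."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polkmap import (SimulationConfig, SimulatedGenome, export_fixture,
                     generate_genome, make_bins, repliseq_counts, sample_fragments)
from polkmap.io import read_bedgraph, read_fragments_bed
from polkmap.simulate import capture_weights


def two_tile_genome(z_gc):
    """Minimal hand-built genome: one chromosome, two 1 kb tiles."""
    grid = make_bins({"chr1": 2_000}, 1_000)
    latent = {"gc": np.asarray(z_gc, dtype=float)}
    return SimulatedGenome(chrom_sizes=(("chr1", 2_000),), tile_size=1_000,
                           tile_grid=grid, latent=latent,
                           genes=pd.DataFrame(), repeats=pd.DataFrame())


class TestConfig:
    def test_fragment_length_invariants(self):
        with pytest.raises(ValueError, match="min <= mean <= max"):
            SimulationConfig(chrom_sizes={"chr1": 10_000}, frag_len_mean=600)

    def test_chromosome_must_exceed_fragment_max(self):
        with pytest.raises(ValueError, match="longer than"):
            SimulationConfig(chrom_sizes={"chr1": 400})

    def test_chromosome_shorter_than_tile_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            SimulationConfig(chrom_sizes={"chr1": 800}, tile_size=1_000,
                             frag_len_min=10, frag_len_mean=20, frag_len_max=30)

    def test_unknown_effect_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimulationConfig(chrom_sizes={"chr1": 10_000},
                             effect_sizes={"not_a_feature": 1.0})


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(chrom_sizes={"chr1": 100_000}, seed=1)
        a, b = generate_genome(cfg), generate_genome(cfg)
        for name in a.latent:
            np.testing.assert_array_equal(a.latent[name], b.latent[name])
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.repeats, b.repeats)

    def test_no_genes_means_no_promoters(self):
        cfg = SimulationConfig(chrom_sizes={"chr1": 100_000},
                               feature_params={"gene_count": 0})
        g = generate_genome(cfg)
        assert len(g.genes) == 0
        assert not g.latent["promoter"].any()

    def test_infinite_gc_autocorr_gives_constant_per_chromosome(self):
        """Infinite smoothing length degenerates to the constant-fill oracle."""
        cfg = SimulationConfig(chrom_sizes={"chr1": 80_000, "chr2": 40_000},
                               feature_params={"gc_autocorr": np.inf}, seed=3)
        g = generate_genome(cfg)
        for chrom in ("chr1", "chr2"):
            vals = g.latent["gc"][g.tile_grid.chroms == chrom]
            np.testing.assert_array_equal(vals, np.full(vals.size, vals[0]))

    def test_latent_invariants(self, small_experiment):
        _, g = small_experiment
        for name, vals in g.latent.items():
            assert np.all(np.isfinite(vals)), name
        for name in ("gc", "sine_density", "line_density", "open_chromatin"):
            assert g.latent[name].min() >= 0 and g.latent[name].max() <= 1
        assert (g.latent["active_mark"] >= 0).all()
        sizes = dict(g.chrom_sizes)
        for _, r in g.repeats.iterrows():
            assert 0 <= r["start"] < r["end"] <= sizes[r["chrom"]]

    def test_bed12_block_consistency(self, small_experiment):
        _, g = small_experiment
        assert len(g.genes) > 0
        for _, gene in g.genes.iterrows():
            sizes = [int(s) for s in gene["blockSizes"].rstrip(",").split(",")]
            starts = [int(s) for s in gene["blockStarts"].rstrip(",").split(",")]
            assert len(sizes) == len(starts) == gene["blockCount"]
            assert starts[0] == 0
            assert starts[-1] + sizes[-1] == gene["end"] - gene["start"]
            assert all(starts[i] + sizes[i] <= starts[i + 1]
                       for i in range(len(starts) - 1))

    def test_sequence_matches_latent_gc(self):
        cfg = SimulationConfig(chrom_sizes={"chr1": 50_000}, emit_sequence=True, seed=5)
        g = generate_genome(cfg)
        grid = g.tile_grid
        seq = g.sequence["chr1"]
        for i in range(grid.n_bins):
            tile = seq[grid.starts[i]:grid.ends[i]]
            frac = sum(b in "GC" for b in tile) / len(tile)
            assert abs(frac - g.latent["gc"][i]) <= 0.05


class TestSampleFragments:
    def test_deterministic_and_replicate_specific(self, small_experiment):
        cfg, g = small_experiment
        a = sample_fragments(g, cfg, "treated", 1)
        b = sample_fragments(g, cfg, "treated", 1)
        np.testing.assert_array_equal(a.starts, b.starts)
        c = sample_fragments(g, cfg, "treated", 2)
        assert not np.array_equal(a.starts, c.starts)

    def test_fragment_invariants(self, small_experiment):
        cfg, g = small_experiment
        fs = sample_fragments(g, cfg, "treated", 1)
        lens = fs.ends - fs.starts
        assert fs.n_fragments == cfg.library_size
        assert lens.min() >= cfg.frag_len_min and lens.max() <= cfg.frag_len_max
        sizes = dict(cfg.chrom_sizes)
        for chrom, starts, ends in fs.by_chrom():
            assert starts.min() >= 0 and ends.max() <= sizes[chrom]

    def test_zero_library_size(self, small_experiment):
        cfg, g = small_experiment
        from dataclasses import replace
        fs = sample_fragments(g, replace(cfg, library_size=0), "control", 1)
        assert fs.n_fragments == 0

    def test_invalid_condition_rejected(self, small_experiment):
        cfg, g = small_experiment
        with pytest.raises(ValueError, match="condition"):
            sample_fragments(g, cfg, "mock", 1)

    def test_null_betas_give_uniform_tile_occupancy(self):
        """With all beta = 0 treated sampling is uniform over tiles (chi-square)."""
        cfg = SimulationConfig(chrom_sizes={"chr1": 200_000}, library_size=100_000,
                               effect_sizes={}, seed=2)
        g = generate_genome(cfg)
        fs = sample_fragments(g, cfg, "treated", 1)
        mids = (fs.starts + fs.ends) // 2
        counts = np.bincount(mids // cfg.tile_size, minlength=g.tile_grid.n_bins)
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_capture_ratio_matches_closed_form(self):
        """Two tiles with z = (1, 0), beta = 1: count ratio converges to e."""
        g = two_tile_genome([1.0, 0.0])
        cfg = SimulationConfig(chrom_sizes={"chr1": 2_000}, library_size=1_000_000,
                               effect_sizes={"gc": 1.0}, frag_len_min=50,
                               frag_len_mean=60, frag_len_max=80, seed=4)
        fs = sample_fragments(g, cfg, "treated", 1)
        mids = (fs.starts + fs.ends) // 2
        n1 = int((mids < 1_000).sum())
        n = cfg.library_size
        p = np.e / (1 + np.e)  # closed-form oracle for the tile-1 probability
        assert abs(n1 - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_all_zero_weights_rejected(self, monkeypatch):
        g = two_tile_genome([0.0, 0.0])
        cfg = SimulationConfig(chrom_sizes={"chr1": 2_000}, library_size=10,
                               frag_len_min=50, frag_len_mean=60, frag_len_max=80)
        assert np.all(capture_weights(g, {"gc": 1.0}) > 0)
        import polkmap.simulate as sim
        monkeypatch.setattr(sim, "capture_weights", lambda *a, **k: np.zeros(2))
        with pytest.raises(ValueError, match="zero"):
            sim.sample_fragments(g, cfg, "treated", 1)


class TestRepliseq:
    def test_recovered_timing_tracks_latent(self):
        cfg = SimulationConfig(chrom_sizes={"chr1": 2_000_000}, seed=6)
        g = generate_genome(cfg)
        grid = make_bins(dict(cfg.chrom_sizes), 50_000)
        early, late = repliseq_counts(g, grid, depth=400_000, seed=6)
        from polkmap import replication_score, spearman, aggregate_signal_mean
        rec = replication_score(early, late)
        latent = aggregate_signal_mean(g.feature_steps("replication_timing"), grid)
        assert spearman(rec.values, latent.values) > 0.9


class TestExportFixture:
    def test_round_trip_and_manifest(self, small_experiment, tmp_path):
        cfg, g = small_experiment
        sets = [sample_fragments(g, cfg, "treated", 1),
                sample_fragments(g, cfg, "control", 1)]
        manifest = export_fixture(g, sets, tmp_path, config=cfg)
        assert len(manifest["libraries"]) == 2
        for entry, fs in zip(manifest["libraries"], sets):
            back = read_fragments_bed(tmp_path / entry["file"],
                                      fs.condition, fs.replicate_id)
            np.testing.assert_array_equal(back.starts, fs.starts)
            np.testing.assert_array_equal(back.ends, fs.ends)
            np.testing.assert_array_equal(back.chroms, fs.chroms)

    def test_gc_bedgraph_round_trips_exactly(self, small_experiment, tmp_path):
        cfg, g = small_experiment
        export_fixture(g, [], tmp_path, config=cfg)
        df = read_bedgraph(tmp_path / "feature_gc.bedGraph")
        np.testing.assert_array_equal(df["value"].to_numpy(), g.latent["gc"])

    def test_exports_are_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(chrom_sizes={"chr1": 200_000}, library_size=5_000,
                               n_treated_reps=1, seed=9)
        for sub in ("a", "b"):
            g = generate_genome(cfg)
            sets = [sample_fragments(g, cfg, "treated", 1),
                    sample_fragments(g, cfg, "control", 1)]
            export_fixture(g, sets, tmp_path / sub, config=cfg)
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
        assert not cmp.diff_files and not cmp.left_only and not cmp.right_only
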