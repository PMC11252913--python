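"""Simulate a small capture-sequencing experiment and export it as text files.

Builds a 5 Mb toy genome with latent feature tracks (GC, open chromatin,
histone marks, repeats, replication timing), samples two treated libraries
whose fragment capture follows the planted log-linear model plus one
unbiased control, and writes everything (chrom.sizes, bedGraphs, BED
annotations, fragment BEDs, ground-truth betas, manifest) to
scratch/example_fixture/.
"""

from polkmap import SimulationConfig, export_fixture, generate_genome, sample_fragments

cfg = SimulationConfig(chrom_sizes={"chr1": 4_000_000, "chr2": 1_000_000},
                       library_size=50_000, n_treated_reps=2, seed=42)
genome = generate_genome(cfg)
libraries = [sample_fragments(genome, cfg, "treated", r) for r in (1, 2)]
libraries.append(sample_fragments(genome, cfg, "control", 1))

manifest = export_fixture(genome, libraries, "scratch/example_fixture", config=cfg)

print(f"genome: {sum(l for _, l in cfg.chrom_sizes):,} bp, "
      f"{genome.tile_grid.n_bins:,} tiles of {cfg.tile_size} bp")
print(f"annotations: {len(genome.genes)} genes, {len(genome.repeats)} repeat elements")
for lib in manifest["libraries"]:
    print(f"library {lib['condition']} rep{lib['replicate_id']}: "
          f"{lib['n_fragments']:,} fragments -> {lib['file']}")
# The planted betas in ground_truth_betas.tsv are what downstream analysis
# should recover as correlation signs; fragments are 200-500 bp inserts.
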