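"""Replicate-wise Spearman correlation of enrichment vs genomic features.

Reproduces the R ± SD summary of the assay on synthetic data: six treated
replicates are correlated against each latent feature aggregated to the
50 kb grid, and the report is sorted by |mean rho|.  Because the capture
betas are planted, the recovered signs are known in advance.
"""

from polkmap import (SimulationConfig, aggregate_signal_mean, correlate_replicates,
                     correlation_report, count_fragments, generate_genome,
                     log2_enrichment, make_bins, normalize_total, sample_fragments)

cfg = SimulationConfig(chrom_sizes={"chr1": 50_000_000}, library_size=200_000, seed=0)
genome = generate_genome(cfg)
grid = make_bins(dict(cfg.chrom_sizes), 50_000)

control = normalize_total(count_fragments(
    sample_fragments(genome, cfg, "control", 1), grid))
tracks = [log2_enrichment(normalize_total(count_fragments(
    sample_fragments(genome, cfg, "treated", rep), grid)), control)
    for rep in range(1, 7)]

summaries = []
for name in ("gc", "open_chromatin", "active_mark", "repressive_mark",
             "sine_density", "line_density"):
    fv = aggregate_signal_mean(genome.feature_steps(name), grid, name)
    summaries.append(correlate_replicates(tracks, fv))

report = correlation_report(summaries)
print(report[["feature", "mean_rho", "sd_rho", "n_bins_used"]].to_string(index=False))
print("\nplanted betas:", dict(cfg.effect_sizes))
# Each row is mean +/- SD of Spearman rho over the six replicates; the sign
# of every rho with |beta| >= 0.2 matches its planted coefficient, and
# active-chromatin features rank above the repressive mark.
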