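"""Run the whole pipeline from files, the way a real dataset would be processed.

Exports a simulated fixture to disk, writes a pipeline configuration that
points at those files (fragment BEDs per replicate, chrom.sizes, feature
tracks, gene models), and runs count -> normalize -> enrich -> mask ->
correlate -> profile in one call, leaving bedGraph/TSV outputs and a JSON
manifest under scratch/example_pipeline/.
"""

import json
from pathlib import Path

from polkmap import (PipelineConfig, SimulationConfig, export_fixture,
                     generate_genome, run_pipeline, sample_fragments)

fixture = Path("scratch/example_pipeline/fixture")
cfg = SimulationConfig(chrom_sizes={"chr1": 5_000_000}, library_size=50_000,
                       n_treated_reps=3, seed=11)
genome = generate_genome(cfg)
libs = [sample_fragments(genome, cfg, "treated", r) for r in (1, 2, 3)]
libs.append(sample_fragments(genome, cfg, "control", 1))
export_fixture(genome, libs, fixture, config=cfg)

pipeline = PipelineConfig(
    chrom_sizes_path=str(fixture / "chrom.sizes"),
    fragments={"treated": {r: str(fixture / f"fragments_treated_rep{r}.bed")
                           for r in (1, 2, 3)},
               "control": {1: str(fixture / "fragments_control_rep1.bed")}},
    outdir="scratch/example_pipeline/out",
    bin_width=50_000,
    features=[
        {"name": "gc", "path": str(fixture / "feature_gc.bedGraph"),
         "mode": "signal_mean"},
        {"name": "active_mark", "path": str(fixture / "feature_active_mark.bedGraph"),
         "mode": "signal_mean"},
        {"name": "repeats", "path": str(fixture / "repeats.bed"),
         "mode": "coverage_fraction"},
    ],
    profiles=[{"label": "tss", "anchors": str(fixture / "genes.bed12"),
               "which": "tss", "flank": 5_000, "step": 100}],
)
manifest = run_pipeline(pipeline)

print("outputs:")
print(json.dumps(manifest["outputs"], indent=2))
print("\ncorrelation report:")
print(Path("scratch/example_pipeline/out/correlations.tsv").read_text())
# One enrichment bedGraph per treated replicate plus the aggregate track; the
# correlation TSV lists mean +/- SD Spearman rho per feature over replicates.
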