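"""Anchor-centered enrichment profiles: TSS/TES and repeat boundaries.

Plants a promoter capture boost (beta_promoter = 1 within +/-1 kb of each
TSS), computes fine-step coverage for pooled treated and control libraries,
and prints the profile contrast at the TSS versus the TES, plus
SINE/LINE-boundary profiles under the default planted betas.
"""

import numpy as np

from polkmap import (SimulationConfig, fine_coverage, generate_genome,
                     profile_around_anchors, sample_fragments)
from polkmap.profiles import anchors_from_genes, anchors_from_intervals
from polkmap.simulate import FragmentSet


def pool(sets):
    return FragmentSet(condition="treated", replicate_id=0,
                       chroms=np.concatenate([s.chroms for s in sets]),
                       starts=np.concatenate([s.starts for s in sets]),
                       ends=np.concatenate([s.ends for s in sets]))


cfg = SimulationConfig(chrom_sizes={"chr1": 30_000_000}, library_size=200_000,
                       n_treated_reps=2, effect_sizes={"promoter": 1.0},
                       feature_params={"gene_count": 200}, seed=1)
genome = generate_genome(cfg)
sizes = dict(cfg.chrom_sizes)
tcov = fine_coverage(pool([sample_fragments(genome, cfg, "treated", r)
                           for r in (1, 2)]), sizes, step=100)
ccov = fine_coverage(sample_fragments(genome, cfg, "control", 1), sizes, step=100)

for which in ("TSS", "TES"):
    anchors = anchors_from_genes(genome.genes, which)
    res = profile_around_anchors(tcov, ccov, anchors, flank=10_000)
    near = np.abs(res.offsets) <= 1_000
    far = np.abs(res.offsets) >= 5_000
    print(f"{which}: {anchors.n_anchors} anchors, "
          f"mean log2 within 1 kb {res.mean_value[near].mean():+.3f}, "
          f"at 5-10 kb {res.mean_value[far].mean():+.3f}")
# The TSS profile peaks at offset 0 (promoter capture boost); the TES profile
# stays flat because no signal was planted there.

cfg2 = SimulationConfig(chrom_sizes={"chr1": 20_000_000}, library_size=200_000,
                        n_treated_reps=2, seed=2)
genome2 = generate_genome(cfg2)
sizes2 = dict(cfg2.chrom_sizes)
tcov2 = fine_coverage(pool([sample_fragments(genome2, cfg2, "treated", r)
                            for r in (1, 2)]), sizes2, step=50)
ccov2 = fine_coverage(sample_fragments(genome2, cfg2, "control", 1), sizes2, step=50)

for cls in ("SINE", "LINE"):
    reps = genome2.repeats[genome2.repeats["name"] == cls]
    anchors = anchors_from_intervals(reps, "start", label=cls)
    res = profile_around_anchors(tcov2, ccov2, anchors, flank=2_000)
    inside = (res.offsets >= 0) & (res.offsets <= 150 if cls == "SINE"
                                   else res.offsets <= 1_000)
    outside = res.offsets <= -1_000
    print(f"{cls}: {anchors.n_anchors} elements, interior "
          f"{res.mean_value[inside].mean():+.3f} vs upstream flank "
          f"{res.mean_value[outside].mean():+.3f} (log2)")
# SINE interiors sit above their flanks (planted beta > 0) while LINE
# interiors sit below (planted beta < 0), mirroring the assay's repeat story.
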