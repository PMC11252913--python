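import numpy as np
import pytest

from polkmap import FragmentSet, SimulationConfig, generate_genome, make_bins


def make_fragments(rows, condition="treated", replicate_id=1):
    """Build a FragmentSet from (chrom, start, end) tuples."""
    if rows:
        chroms, starts, ends = zip(*rows)
    else:
        chroms, starts, ends = (), (), ()
    return FragmentSet(condition=condition, replicate_id=replicate_id,
                       chroms=np.asarray(chroms, dtype=object),
                       starts=np.asarray(starts, dtype=np.int64),
                       ends=np.asarray(ends, dtype=np.int64))


@pytest.fixture
def toy_grid():
    """Three 50 kb bins on one 150 kb chromosome."""
    return make_bins({"chr1": 150_000}, 50_000)


@pytest.fixture(scope="session")
def small_experiment():
    """A cheap 2 Mb simulated experiment shared by read-only tests."""
    cfg = SimulationConfig(chrom_sizes={"chr1": 1_500_000, "chr2": 500_000},
                           library_size=20_000, n_treated_reps=2, seed=7)
    genome = generate_genome(cfg)
    return cfg, genome
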