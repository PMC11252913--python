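"""Synthetic genomes and fragment libraries with planted capture enrichment.

The generator builds a toy genome carrying the latent feature families a
polymerase-activity capture assay is correlated against — GC content, open
chromatin, active and repressive histone marks, SINE/LINE repeat density,
replication timing (as log2(E/L)) and promoter proximity — together with
BED12 gene models and repeat interval annotations.  Treated libraries draw
fragment midpoints from tiles with probability proportional to

    w(t) = exp( sum_f  beta_f * z_f(t) )

where ``z_f(t)`` is the latent value of feature ``f`` on tile ``t`` and the
``beta_f`` are the planted log-linear effect sizes; control libraries draw
uniformly over tiles (``w = 1``), modeling sequencing of input DNA with no
capture bias.  Because the capture model is exact at tile level, every
downstream stage can be verified by parameter recovery: the sign and
ordering of the planted betas must reappear in the measured correlations.

Fragment lengths follow a truncated normal on the assay's 200-500 bp shear
range; the default design is six treated biological replicates plus one
untreated control.  Identical configuration and seed reproduce bit-identical
output: the master seed is expanded through a fixed counter scheme
(genome = (seed, 0); library = (seed, 1, condition-code, replicate)).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .binning import BinGrid, BinnedTrack, make_bins

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "FragmentSet",
    "generate_genome",
    "sample_fragments",
    "repliseq_counts",
    "export_fixture",
    "DEFAULT_EFFECT_SIZES",
    "DEFAULT_FEATURE_PARAMS",
]

LATENT_FEATURES = (
    "gc", "open_chromatin", "active_mark", "repressive_mark",
    "replication_timing", "sine_density", "line_density", "promoter",
)

# Planted log-linear capture coefficients: positive on GC, open chromatin and
# active marks, weakly positive on the repressive mark, positive on SINE and
# negative on LINE density — the sign structure the assay reports.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "gc": 0.8,
    "open_chromatin": 0.6,
    "active_mark": 0.5,
    "repressive_mark": 0.1,
    "sine_density": 0.5,
    "line_density": -0.2,
    "replication_timing": 0.0,
    "promoter": 0.0,
}

DEFAULT_FEATURE_PARAMS: dict[str, float] = {
    # GC: smoothed noise mapped into [0.05, 0.95] around a genomic mean
    "gc_autocorr": 20_000.0,      # bp; np.inf -> constant per chromosome
    "gc_mean": 0.45,
    "gc_amp": 0.18,
    # open chromatin: sparse peak intervals placed with smoothly clustered
    # intensity (accessibility is regional), per-tile coverage fraction
    "open_peak_per_bp": 1.0 / 20_000.0,
    "open_peak_len_min": 500.0,
    "open_peak_len_max": 2_000.0,
    "open_cluster_autocorr": 200_000.0,
    "open_cluster_strength": 1.0,
    # histone marks: softplus of smoothed standardized noise (>= 0)
    "mark_autocorr": 10_000.0,
    # replication timing: smoothed standardized noise * sd, on log2(E/L) scale
    "timing_autocorr": 100_000.0,
    "timing_sd": 1.0,
    # genes: count apportioned by chromosome length, non-overlapping
    "gene_count": 100.0,
    "gene_len_min": 20_000.0,
    "gene_len_max": 100_000.0,
    "gene_gap_min": 20_000.0,
    "gene_gap_max": 80_000.0,
    "promoter_halfwidth": 1_000.0,
    # repeats: coverage targets and element lengths, with smoothly clustered
    # placement intensity (repeat families are regionally clustered in real
    # genomes, which gives bin-level density variance at 50 kb)
    "sine_coverage": 0.13,
    "sine_len_min": 150.0,
    "sine_len_max": 450.0,
    "line_coverage": 0.20,
    "line_len_min": 2_000.0,
    "line_len_max": 6_000.0,
    "simple_coverage": 0.02,
    "simple_len_min": 50.0,
    "simple_len_max": 500.0,
    "repeat_cluster_autocorr": 200_000.0,
    "repeat_cluster_strength": 0.8,
}

_CONDITION_CODES = {"treated": 1, "control": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic experiment.

    Defaults describe the study design the package targets: six treated
    biological replicates plus one untreated control, 200-500 bp fragments
    (truncated normal, mean 330 sd 60), 1 kb latent tiles, and the default
    planted effect sizes.
    """

    chrom_sizes: tuple[tuple[str, int], ...]
    tile_size: int = 1_000
    n_treated_reps: int = 6
    n_control_reps: int = 1
    library_size: int = 200_000
    frag_len_min: int = 200
    frag_len_max: int = 500
    frag_len_mean: float = 330.0
    frag_len_sd: float = 60.0
    effect_sizes: tuple[tuple[str, float], ...] = tuple(DEFAULT_EFFECT_SIZES.items())
    feature_params: tuple[tuple[str, float], ...] = tuple(DEFAULT_FEATURE_PARAMS.items())
    emit_sequence: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.chrom_sizes, Mapping):
            object.__setattr__(self, "chrom_sizes", tuple(self.chrom_sizes.items()))
        else:
            object.__setattr__(self, "chrom_sizes", tuple(self.chrom_sizes))
        if isinstance(self.effect_sizes, Mapping):
            object.__setattr__(self, "effect_sizes", tuple(self.effect_sizes.items()))
        if isinstance(self.feature_params, Mapping):
            merged = dict(DEFAULT_FEATURE_PARAMS)
            merged.update(self.feature_params)
            object.__setattr__(self, "feature_params", tuple(merged.items()))
        self.validate()

    def validate(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must name at least one chromosome")
        if not (0 < self.frag_len_min <= self.frag_len_mean <= self.frag_len_max):
            raise ValueError(
                "fragment lengths must satisfy 0 < min <= mean <= max, got "
                f"min={self.frag_len_min} mean={self.frag_len_mean} max={self.frag_len_max}"
            )
        for name, length in self.chrom_sizes:
            if length <= self.frag_len_max:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) must be longer than "
                    f"frag_len_max ({self.frag_len_max} bp)"
                )
            if length < self.tile_size:
                raise ValueError(
                    f"chromosome {name!r} ({length} bp) is shorter than one "
                    f"tile ({self.tile_size} bp)"
                )
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.n_treated_reps < 1 or self.n_control_reps < 1:
            raise ValueError("need at least one treated and one control replicate")
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")
        for name, _ in self.effect_sizes:
            if name not in LATENT_FEATURES:
                raise ValueError(f"unknown effect-size feature {name!r}; "
                                 f"known: {LATENT_FEATURES}")

    @property
    def betas(self) -> dict[str, float]:
        return dict(self.effect_sizes)

    @property
    def params(self) -> dict[str, float]:
        return dict(self.feature_params)

    def fingerprint(self) -> str:
        """Stable short hash of the full configuration (including seed)."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SimulatedGenome:
    """A toy genome: latent per-tile feature tracks plus annotations."""

    chrom_sizes: tuple[tuple[str, int], ...]
    tile_size: int
    tile_grid: BinGrid
    latent: dict[str, np.ndarray]           # feature name -> one value per tile
    genes: pd.DataFrame                     # BED12 columns
    repeats: pd.DataFrame                   # BED6, class in the name column
    sequence: dict[str, str] | None = None

    def feature_steps(self, name: str) -> Iterator[tuple[str, int, int, float]]:
        """Yield the latent track as bedGraph-style (chrom, start, end, value) steps."""
        vals = self.latent[name]
        g = self.tile_grid
        for i in range(g.n_bins):
            yield (g.chroms[i], int(g.starts[i]), int(g.ends[i]), float(vals[i]))

    def tss_anchors(self):
        from .profiles import anchors_from_genes
        return anchors_from_genes(self.genes, which="TSS")


@dataclass
class FragmentSet:
    """One library's aligned fragments: (chrom, start, end), 0-based half-open."""

    condition: str
    replicate_id: int
    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.condition not in _CONDITION_CODES:
            raise ValueError(f"condition must be 'treated' or 'control', got {self.condition!r}")
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (self.chroms.size == self.starts.size == self.ends.size):
            raise ValueError("chroms/starts/ends length mismatch")
        if self.starts.size and np.any(self.starts >= self.ends):
            raise ValueError("fragments must satisfy start < end")

    @property
    def n_fragments(self) -> int:
        return self.starts.size

    @property
    def label(self) -> str:
        return f"{self.condition}_rep{self.replicate_id}"

    def by_chrom(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (chrom, starts, ends) per chromosome, in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(c, None)
        for chrom in seen:
            sel = self.chroms == chrom
            yield chrom, self.starts[sel], self.ends[sel]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})


# ---------------------------------------------------------------------------
# latent track construction


def _smooth_standardized(rng: np.random.Generator, n_tiles: int,
                         autocorr_bp: float, tile_size: int) -> np.ndarray:
    """Smoothed, re-standardized Gaussian field over one chromosome's tiles.

    Infinite autocorrelation degenerates to a constant per chromosome (one
    draw); otherwise white noise is Gaussian-smoothed with sigma =
    autocorr/tile_size tiles and rescaled back to unit variance.
    """
    if np.isinf(autocorr_bp):
        return np.full(n_tiles, float(rng.standard_normal()))
    noise = rng.standard_normal(n_tiles)
    sigma = autocorr_bp / tile_size
    if sigma <= 0:
        return noise
    sm = gaussian_filter1d(noise, sigma, mode="reflect")
    sd = sm.std()
    if sd == 0:  # single-tile chromosome
        return np.zeros(n_tiles)
    return (sm - sm.mean()) / sd


def _per_chrom_field(rng, grid: BinGrid, autocorr_bp: float, tile_size: int) -> np.ndarray:
    parts = []
    for chrom, _ in grid.chrom_sizes:
        n = int(np.sum(grid.chroms == chrom))
        parts.append(_smooth_standardized(rng, n, autocorr_bp, tile_size))
    return np.concatenate(parts)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _place_elements(rng, grid: BinGrid, intensity: np.ndarray, n_elements: int,
                    len_min: float, len_max: float, chrom_sizes: dict[str, int],
                    class_name: str) -> list[tuple[str, int, int, str]]:
    """Place interval elements with tile-level clustered intensity."""
    if n_elements == 0:
        return []
    p = intensity / intensity.sum()
    tiles = rng.choice(grid.n_bins, size=n_elements, p=p)
    tile_starts = grid.starts[tiles]
    tile_lens = (grid.ends - grid.starts)[tiles]
    offs = rng.integers(0, tile_lens)
    starts = tile_starts + offs
    lens = rng.integers(int(len_min), int(len_max) + 1, size=n_elements)
    out = []
    for i in range(n_elements):
        chrom = grid.chroms[tiles[i]]
        clen = chrom_sizes[chrom]
        s = int(starts[i])
        e = min(s + int(lens[i]), clen)
        if e > s:
            out.append((chrom, s, e, class_name))
    return out


def _coverage_fraction_per_tile(intervals, grid: BinGrid) -> np.ndarray:
    from .features import _union_coverage_per_bin

    if not intervals:
        return np.zeros(grid.n_bins)
    cov = _union_coverage_per_bin(intervals, grid)
    return cov / (grid.ends - grid.starts)


def _make_genes(rng, chrom_sizes, params) -> pd.DataFrame:
    """Non-overlapping stranded BED12 gene models, count apportioned by length."""
    total_count = int(params["gene_count"])
    cols = ["chrom", "start", "end", "name", "score", "strand", "thickStart",
            "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts"]
    rows = []
    if total_count > 0:
        total_len = sum(l for _, l in chrom_sizes)
        gi = 0
        for chrom, clen in chrom_sizes:
            n_here = int(round(total_count * clen / total_len))
            pos = 0
            placed = 0
            while placed < n_here:
                gap = int(rng.integers(int(params["gene_gap_min"]),
                                       int(params["gene_gap_max"]) + 1))
                glen = int(rng.integers(int(params["gene_len_min"]),
                                        int(params["gene_len_max"]) + 1))
                start = pos + gap
                end = start + glen
                if end > clen - int(params["gene_gap_min"]):
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                # 2-4 exon structure obeying BED12 rules: first block starts at
                # 0, last block ends at end-start
                n_blocks = int(rng.integers(2, 5))
                cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_blocks - 2,
                                          replace=False))
                bounds = np.concatenate([[0], cuts, [glen]])
                block_starts = bounds[0::2]
                block_ends = bounds[1::2]
                sizes = block_ends - block_starts
                rows.append((chrom, start, end, f"gene{gi}", 0, strand, start, end,
                             "0", n_blocks,
                             ",".join(str(int(s)) for s in sizes) + ",",
                             ",".join(str(int(s)) for s in block_starts) + ","))
                gi += 1
                placed += 1
                pos = end
    return pd.DataFrame(rows, columns=cols)


def generate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the synthetic genome: latent tracks, genes, repeats, sequence.

    Deterministic under the configuration seed; all latent values are finite,
    GC and repeat densities lie in [0, 1], and annotations respect chromosome
    bounds.
    """
    config.validate()
    params = config.params
    chrom_sizes = dict(config.chrom_sizes)
    grid = make_bins(config.chrom_sizes, config.tile_size)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))

    latent: dict[str, np.ndarray] = {}

    # GC content
    gc_field = _per_chrom_field(rng, grid, params["gc_autocorr"], config.tile_size)
    latent["gc"] = np.clip(params["gc_mean"] + params["gc_amp"] * gc_field, 0.05, 0.95)

    # open chromatin: sparse peaks -> per-tile coverage fraction
    total_len = sum(chrom_sizes.values())
    n_peaks = rng.poisson(total_len * params["open_peak_per_bp"])
    open_cluster = _per_chrom_field(rng, grid, params["open_cluster_autocorr"],
                                    config.tile_size)
    peaks = _place_elements(rng, grid,
                            np.exp(params["open_cluster_strength"] * open_cluster),
                            int(n_peaks),
                            params["open_peak_len_min"], params["open_peak_len_max"],
                            chrom_sizes, "open")
    latent["open_chromatin"] = _coverage_fraction_per_tile(peaks, grid)

    # histone marks: non-negative softplus fields
    latent["active_mark"] = _softplus(
        _per_chrom_field(rng, grid, params["mark_autocorr"], config.tile_size))
    latent["repressive_mark"] = _softplus(
        _per_chrom_field(rng, grid, params["mark_autocorr"], config.tile_size))

    # replication timing on the log2(E/L) scale
    latent["replication_timing"] = params["timing_sd"] * _per_chrom_field(
        rng, grid, params["timing_autocorr"], config.tile_size)

    # repeats with clustered placement intensity
    cluster = _per_chrom_field(rng, grid, params["repeat_cluster_autocorr"],
                               config.tile_size)
    intensity_sine = np.exp(params["repeat_cluster_strength"] * cluster)
    intensity_line = np.exp(-params["repeat_cluster_strength"] * cluster)
    repeat_rows: list[tuple[str, int, int, str]] = []
    for cls, cov_key, lmin, lmax, intensity in (
        ("SINE", "sine_coverage", params["sine_len_min"], params["sine_len_max"], intensity_sine),
        ("LINE", "line_coverage", params["line_len_min"], params["line_len_max"], intensity_line),
        ("simple_repeat", "simple_coverage", params["simple_len_min"],
         params["simple_len_max"], np.ones(grid.n_bins)),
    ):
        mean_len = (lmin + lmax) / 2
        n_el = int(round(total_len * params[cov_key] / mean_len))
        repeat_rows.extend(_place_elements(rng, grid, intensity, n_el, lmin, lmax,
                                           chrom_sizes, cls))
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "name"])
    if len(repeats):
        repeats["score"] = 0
        repeats["strand"] = np.where(rng.random(len(repeats)) < 0.5, "+", "-")
        order = np.lexsort((repeats["start"].to_numpy(),
                            pd.Categorical(repeats["chrom"],
                                           categories=list(chrom_sizes)).codes))
        repeats = repeats.iloc[order].reset_index(drop=True)
    else:
        repeats["score"] = pd.Series(dtype=int)
        repeats["strand"] = pd.Series(dtype=str)
    sine = repeats[repeats["name"] == "SINE"][["chrom", "start", "end"]]
    line = repeats[repeats["name"] == "LINE"][["chrom", "start", "end"]]
    latent["sine_density"] = _coverage_fraction_per_tile(
        list(sine.itertuples(index=False, name=None)), grid)
    latent["line_density"] = _coverage_fraction_per_tile(
        list(line.itertuples(index=False, name=None)), grid)

    # genes and promoter-proximity indicator
    genes = _make_genes(rng, config.chrom_sizes, params)
    promoter = np.zeros(grid.n_bins)
    if len(genes):
        hw = int(params["promoter_halfwidth"])
        prom_iv = []
        for _, g in genes.iterrows():
            tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
            clen = chrom_sizes[g["chrom"]]
            prom_iv.append((g["chrom"], max(0, tss - hw), min(clen, tss + hw + 1)))
        cov = _coverage_fraction_per_tile(prom_iv, grid)
        promoter = (cov > 0).astype(float)
    latent["promoter"] = promoter

    for name, vals in latent.items():
        if not np.all(np.isfinite(vals)):
            raise AssertionError(f"non-finite latent values in {name}")

    sequence = None
    if config.emit_sequence:
        sequence = {}
        for chrom, clen in config.chrom_sizes:
            sel = np.flatnonzero(grid.chroms == chrom)
            parts = []
            for i in sel:
                tlen = int(grid.ends[i] - grid.starts[i])
                n_gc = int(round(latent["gc"][i] * tlen))
                bases = np.empty(tlen, dtype="S1")
                gc_pos = rng.permutation(tlen)
                gc_choice = rng.integers(0, 2, size=tlen)
                at_choice = rng.integers(0, 2, size=tlen)
                bases[:] = np.where(at_choice == 0, b"A", b"T")
                idx = gc_pos[:n_gc]
                bases[idx] = np.where(gc_choice[idx] == 0, b"G", b"C")
                parts.append(bases.tobytes().decode("ascii"))
            sequence[chrom] = "".join(parts)

    return SimulatedGenome(chrom_sizes=config.chrom_sizes, tile_size=config.tile_size,
                           tile_grid=grid, latent=latent, genes=genes,
                           repeats=repeats, sequence=sequence)


# ---------------------------------------------------------------------------
# fragment sampling


def capture_weights(genome: SimulatedGenome, betas: Mapping[str, float]) -> np.ndarray:
    """Per-tile capture weights w(t) = exp(sum_f beta_f z_f(t))."""
    logw = np.zeros(genome.tile_grid.n_bins)
    for name, beta in betas.items():
        if beta == 0:
            continue
        if name not in genome.latent:
            raise ValueError(f"unknown latent feature {name!r}")
        logw += beta * genome.latent[name]
    logw -= logw.max()  # overflow guard; weights are defined up to a constant
    return np.exp(logw)


def sample_fragments(genome: SimulatedGenome, config: SimulationConfig,
                     condition: str, replicate_id: int) -> FragmentSet:
    """Draw one library of fragments under the planted capture model.

    Treated libraries sample fragment-midpoint tiles with probability
    proportional to the capture weight; control libraries sample uniformly
    over tiles.  The midpoint is jittered uniformly within the tile and the
    fragment length drawn from the truncated normal; fragments are shifted
    (never truncated) to stay within chromosome bounds, so the length
    invariants hold exactly.  Deterministic under (seed, condition,
    replicate_id).
    """
    if condition not in _CONDITION_CODES:
        raise ValueError(f"condition must be 'treated' or 'control', got {condition!r}")
    grid = genome.tile_grid
    if condition == "treated":
        w = capture_weights(genome, config.betas)
    else:
        w = np.ones(grid.n_bins)
    if not np.any(w > 0):
        raise ValueError("all capture weights are zero; cannot sample fragments")

    seed_seq = np.random.SeedSequence(
        (config.seed, 1, _CONDITION_CODES[condition], replicate_id))
    rng = np.random.default_rng(seed_seq)
    n = config.library_size
    if n == 0:
        return FragmentSet(condition=condition, replicate_id=replicate_id,
                           chroms=np.empty(0, dtype=object),
                           starts=np.empty(0, dtype=np.int64),
                           ends=np.empty(0, dtype=np.int64),
                           config_fingerprint=config.fingerprint())

    p = w / w.sum()
    tiles = rng.choice(grid.n_bins, size=n, p=p)
    tile_lens = (grid.ends - grid.starts)[tiles]
    mids = grid.starts[tiles] + rng.integers(0, tile_lens)

    a = (config.frag_len_min - config.frag_len_mean) / config.frag_len_sd
    b = (config.frag_len_max - config.frag_len_mean) / config.frag_len_sd
    lens = stats.truncnorm.rvs(a, b, loc=config.frag_len_mean,
                               scale=config.frag_len_sd, size=n, random_state=rng)
    lens = np.clip(np.rint(lens).astype(np.int64),
                   config.frag_len_min, config.frag_len_max)

    starts = mids - lens // 2
    ends = starts + lens
    sizes = dict(genome.chrom_sizes)
    chrom_len_per_tile = np.array([sizes[c] for c in grid.chroms], dtype=np.int64)
    chrom_lens = chrom_len_per_tile[tiles]
    shift_left = np.maximum(0, -starts)
    starts += shift_left
    ends += shift_left
    shift_right = np.maximum(0, ends - chrom_lens)
    starts -= shift_right
    ends -= shift_right

    chroms = grid.chroms[tiles]
    chrom_order = {c: i for i, (c, _) in enumerate(genome.chrom_sizes)}
    code_per_tile = np.array([chrom_order[c] for c in grid.chroms], dtype=np.int64)
    codes = code_per_tile[tiles]
    order = np.lexsort((ends, starts, codes))
    return FragmentSet(condition=condition, replicate_id=replicate_id,
                       chroms=chroms[order], starts=starts[order], ends=ends[order],
                       config_fingerprint=config.fingerprint())


def repliseq_counts(genome: SimulatedGenome, grid: BinGrid, depth: int,
                    seed: int = 0) -> tuple[BinnedTrack, BinnedTrack]:
    """Early/late S-phase count tracks consistent with the latent timing score.

    The latent replication-timing track is interpreted as log2(E/L); early
    reads are drawn from tiles with weight 2^(timing/2) and late reads with
    weight 2^(-timing/2), then counted on ``grid``, so the recovered
    log2(E/L) matches the latent track up to sampling noise.
    """
    timing = genome.latent["replication_timing"]
    tgrid = genome.tile_grid
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    out = []
    for sign in (+1.0, -1.0):
        w = np.power(2.0, sign * timing / 2.0)
        counts_tile = rng.multinomial(depth, w / w.sum())
        counts = np.zeros(grid.n_bins, dtype=np.int64)
        for i in np.flatnonzero(counts_tile):
            mid = (tgrid.starts[i] + tgrid.ends[i]) // 2
            counts[grid.bin_index(tgrid.chroms[i], mid)] += counts_tile[i]
        label = "early" if sign > 0 else "late"
        out.append(BinnedTrack(grid=grid, values=counts, kind="raw_count", label=label))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# fixture export


def export_fixture(genome: SimulatedGenome, fragment_sets, outdir,
                   config: SimulationConfig | None = None) -> dict:
    """Write the simulated experiment as plain-text files plus a manifest.

    Emits chrom.sizes, one bedGraph per latent feature, repeats BED6, genes
    BED12, one fragment BED3 per library, the ground-truth beta table and a
    JSON manifest; every file round-trips losslessly through the io module.
    """
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "libraries": []}

    path = outdir / "chrom.sizes"
    pio.write_chrom_sizes(dict(genome.chrom_sizes), path)
    manifest["files"]["chrom_sizes"] = path.name

    manifest["files"]["features"] = {}
    for name in LATENT_FEATURES:
        p = outdir / f"feature_{name}.bedGraph"
        pio.write_bedgraph_steps(genome.feature_steps(name), p)
        manifest["files"]["features"][name] = p.name

    p = outdir / "repeats.bed"
    pio.write_bed(genome.repeats, p)
    manifest["files"]["repeats"] = p.name

    p = outdir / "genes.bed12"
    pio.write_bed(genome.genes, p)
    manifest["files"]["genes"] = p.name

    for fs in fragment_sets:
        p = outdir / f"fragments_{fs.condition}_rep{fs.replicate_id}.bed"
        pio.write_fragments_bed(fs, p)
        manifest["libraries"].append({
            "condition": fs.condition, "replicate_id": int(fs.replicate_id),
            "file": p.name, "n_fragments": int(fs.n_fragments),
        })

    if config is not None:
        p = outdir / "ground_truth_betas.tsv"
        pd.DataFrame(sorted(config.betas.items()),
                     columns=["feature", "beta"]).to_csv(p, sep="\t", index=False)
        manifest["files"]["betas"] = p.name
        manifest["config_fingerprint"] = config.fingerprint()
        manifest["seed"] = config.seed

    if genome.sequence is not None:
        p = outdir / "genome.fa"
        pio.write_fasta(genome.sequence, p)
        manifest["files"]["fasta"] = p.name

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
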