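"""Feature tracks on the bin grid and replicate-wise Spearman correlation.

Genomic features come in two shapes: interval annotations (open-chromatin
peaks, SINE/LINE repeats) and stepwise signal (histone-mark or replication-
timing bedGraphs).  Both are aggregated onto the enrichment bin grid —
intervals as union coverage fraction, signal as base-pair-weighted mean —
and correlated with each replicate's log2 enrichment track by Spearman's
rho.  The cross-replicate mean ± sample SD is the "R ± SD" summary of the
assay.  All per-bin aggregation is exact integer/float arithmetic via
cumulative-coverage functions, so tests can check it against brute-force
per-base oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinGrid, BinnedTrack, log2_enrichment, normalize_total

__all__ = [
    "FeatureVector",
    "CorrelationSummary",
    "aggregate_coverage_fraction",
    "aggregate_signal_mean",
    "gc_fraction_from_sequences",
    "spearman",
    "correlate_replicates",
    "replication_score",
    "correlation_report",
    "spearman_null_band",
]


@dataclass
class FeatureVector:
    """A genomic feature aggregated onto a :class:`~polkmap.binning.BinGrid`."""

    grid: BinGrid
    values: np.ndarray
    feature_name: str
    aggregation_mode: str  # coverage_fraction | signal_mean | gc_fraction | density | log2_ratio
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("feature vector length does not match grid")
        if self.mask is None:
            self.mask = np.ones(self.grid.n_bins, dtype=bool)
        if self.aggregation_mode in ("coverage_fraction", "gc_fraction"):
            valid = self.values[self.mask]
            if valid.size and (valid.min() < 0 or valid.max() > 1):
                raise ValueError(f"{self.aggregation_mode} values must lie in [0, 1]")


@dataclass
class CorrelationSummary:
    """Per-replicate Spearman rho of enrichment vs one feature, with mean ± SD.

    ``sd_rho`` is the sample standard deviation (n−1 denominator) across the
    treated replicates; it is 0 and ``single_replicate`` is True when only one
    replicate was available.
    """

    feature_name: str
    per_replicate_rho: tuple[float, ...]
    mean_rho: float
    sd_rho: float
    n_bins_used: int
    single_replicate: bool = field(default=False)

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate_rho)


# ---------------------------------------------------------------------------
# exact cumulative-coverage aggregation


def _group_by_chrom(intervals: Iterable[tuple],
                    with_value: bool = False) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple]] = {}
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if end <= start:
            raise ValueError(f"zero/negative-length interval {chrom}:{start}-{end}")
        row = (start, end, float(iv[3])) if with_value else (start, end)
        by.setdefault(chrom, []).append(row)
    return {c: np.asarray(v, dtype=float) for c, v in by.items()}


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping intervals (sorted, merged)."""
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    keep_s, keep_e = [], []
    cur_s, cur_e = s[0], e[0]
    for i in range(1, s.size):
        if s[i] <= cur_e:
            cur_e = max(cur_e, e[i])
        else:
            keep_s.append(cur_s)
            keep_e.append(cur_e)
            cur_s, cur_e = s[i], e[i]
    keep_s.append(cur_s)
    keep_e.append(cur_e)
    return np.asarray(keep_s), np.asarray(keep_e)


def _cum_at(x: np.ndarray, s: np.ndarray, e: np.ndarray,
            weights: np.ndarray | None = None) -> np.ndarray:
    """(Weighted) covered base pairs in [0, x) for sorted disjoint intervals.

    C(x) = sum_j w_j * clamp(x - s_j, 0, e_j - s_j); evaluated exactly for an
    array of boundary positions x.
    """
    lens = e - s
    w = lens if weights is None else lens * weights
    cum = np.concatenate([[0.0], np.cumsum(w)])
    k = np.searchsorted(s, x, side="right") - 1  # last interval starting at or before x
    kc = np.maximum(k, 0)
    frac = np.clip(x - s[kc], 0, lens[kc])
    if weights is not None:
        frac = frac * weights[kc]
    return np.where(k >= 0, cum[kc] + frac, 0.0)


def _union_coverage_per_bin(intervals: Iterable[tuple], grid: BinGrid) -> np.ndarray:
    """Base pairs of each bin covered by the union of ``intervals``."""
    cov = np.zeros(grid.n_bins)
    for chrom, arr in _group_by_chrom(intervals).items():
        if chrom not in grid.offsets:
            continue
        s, e = _merge(arr[:, 0], arr[:, 1])
        sel = grid.chroms == chrom
        cov[sel] = _cum_at(grid.ends[sel].astype(float), s, e) - _cum_at(
            grid.starts[sel].astype(float), s, e
        )
    return cov


def aggregate_coverage_fraction(intervals: Iterable[tuple], grid: BinGrid,
                                feature_name: str = "") -> FeatureVector:
    """Fraction of each bin covered by the union of the given intervals.

    Overlapping and duplicate intervals are unioned, not summed, so the value
    is a true coverage fraction in [0, 1].
    """
    cov = _union_coverage_per_bin(intervals, grid)
    frac = cov / (grid.ends - grid.starts)
    return FeatureVector(grid=grid, values=frac, feature_name=feature_name,
                         aggregation_mode="coverage_fraction")


def aggregate_signal_mean(signal: Iterable[tuple], grid: BinGrid,
                          feature_name: str = "") -> FeatureVector:
    """Base-pair-weighted mean of a stepwise (bedGraph-style) signal per bin.

    ``signal`` yields ``(chrom, start, end, value)`` steps that must not
    overlap one another.  Bases not covered by any step contribute value 0 to
    the mean (the bin mean is over the full bin length).
    """
    out = np.zeros(grid.n_bins)
    for chrom, arr in _group_by_chrom(signal, with_value=True).items():
        if chrom not in grid.offsets:
            continue
        order = np.argsort(arr[:, 0], kind="stable")
        s, e, v = arr[order, 0], arr[order, 1], arr[order, 2]
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"overlapping signal intervals on {chrom}")
        sel = grid.chroms == chrom
        w_hi = _cum_at(grid.ends[sel].astype(float), s, e, weights=v)
        w_lo = _cum_at(grid.starts[sel].astype(float), s, e, weights=v)
        out[sel] = (w_hi - w_lo) / (grid.ends[sel] - grid.starts[sel])
    return FeatureVector(grid=grid, values=out, feature_name=feature_name,
                         aggregation_mode="signal_mean")


_GC_BYTES = frozenset(b"GCgcSs")
_N_BYTES = frozenset(b"Nn")


def gc_fraction_from_sequences(sequences: Mapping[str, str], grid: BinGrid,
                               feature_name: str = "gc") -> FeatureVector:
    """Per-bin G+C fraction of the genome sequence.

    Case-insensitive; ``N`` bases are excluded from the denominator, and a bin
    whose bases are all ``N`` is masked rather than given a value.
    """
    values = np.zeros(grid.n_bins)
    mask = np.ones(grid.n_bins, dtype=bool)
    gc_lut = np.zeros(256, dtype=np.int64)
    n_lut = np.zeros(256, dtype=np.int64)
    for b in _GC_BYTES:
        gc_lut[b] = 1
    for b in _N_BYTES:
        n_lut[b] = 1
    for chrom, seq in sequences.items():
        if chrom not in grid.offsets:
            continue
        if len(seq) != grid.chrom_length(chrom):
            raise ValueError(
                f"sequence length {len(seq)} != chromosome length "
                f"{grid.chrom_length(chrom)} for {chrom!r}"
            )
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        gc_cum = np.concatenate([[0], np.cumsum(gc_lut[codes])])
        n_cum = np.concatenate([[0], np.cumsum(n_lut[codes])])
        sel = np.flatnonzero(grid.chroms == chrom)
        lo, hi = grid.starts[sel], grid.ends[sel]
        gc = gc_cum[hi] - gc_cum[lo]
        nn = n_cum[hi] - n_cum[lo]
        denom = (hi - lo) - nn
        ok = denom > 0
        values[sel[ok]] = gc[ok] / denom[ok]
        mask[sel[~ok]] = False
    return FeatureVector(grid=grid, values=values, feature_name=feature_name,
                         aggregation_mode="gc_fraction", mask=mask)


# ---------------------------------------------------------------------------
# correlation


def spearman(x: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Spearman's rank correlation of two per-bin vectors on unmasked bins.

    Average ranks are assigned to ties; requires at least 3 unmasked bins and
    non-constant vectors (rank correlation is undefined for a constant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if mask is not None:
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need at least 3 unmasked bins, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def correlate_replicates(enrichment_tracks: Sequence[BinnedTrack],
                         feature: FeatureVector) -> CorrelationSummary:
    """Spearman rho per treated replicate vs one feature, with mean ± sample SD.

    All tracks and the feature must share one grid; each rho is computed on
    the intersection of every track's mask with the feature's mask, so every
    replicate uses the identical bin set (reported as ``n_bins_used``).
    """
    if not enrichment_tracks:
        raise ValueError("need at least one enrichment track")
    grid = enrichment_tracks[0].grid
    for t in enrichment_tracks:
        if t.grid != grid:
            raise ValueError("enrichment tracks are on different grids")
    if feature.grid != grid:
        raise ValueError("feature is on a different grid than the enrichment tracks")
    mask = feature.mask.copy()
    for t in enrichment_tracks:
        mask &= t.mask
    rhos = tuple(spearman(t.values, feature.values, mask) for t in enrichment_tracks)
    mean = float(np.mean(rhos))
    sd = float(np.std(rhos, ddof=1)) if len(rhos) > 1 else 0.0
    return CorrelationSummary(
        feature_name=feature.feature_name,
        per_replicate_rho=rhos,
        mean_rho=mean,
        sd_rho=sd,
        n_bins_used=int(mask.sum()),
        single_replicate=len(rhos) == 1,
    )


def replication_score(early_counts: BinnedTrack, late_counts: BinnedTrack,
                      pseudocount: float = 0.5) -> FeatureVector:
    """Replication-timing score log2(E/L) from early/late S-phase count tracks.

    E and L are each normalized to total count first, so the score is
    invariant to the two libraries' sequencing depths; positive values mean
    early-replicating.
    """
    track = log2_enrichment(normalize_total(early_counts),
                            normalize_total(late_counts), pseudocount)
    return FeatureVector(grid=track.grid, values=track.values,
                         feature_name="replication_timing",
                         aggregation_mode="log2_ratio", mask=track.mask)


def correlation_report(summaries: Sequence[CorrelationSummary],
                       path=None) -> pd.DataFrame:
    """Tabulate correlation summaries, strongest |mean rho| first.

    Ties in |mean rho| are broken alphabetically by feature name; the table
    lists per-replicate rhos, mean, SD and the number of bins used.  Written
    as TSV when ``path`` is given.
    """
    rows = []
    for s in summaries:
        rows.append({
            "feature": s.feature_name,
            "n_replicates": s.n_replicates,
            "mean_rho": s.mean_rho,
            "sd_rho": s.sd_rho,
            "n_bins_used": s.n_bins_used,
            "per_replicate_rho": ",".join(f"{r:.6g}" for r in s.per_replicate_rho),
        })
    df = pd.DataFrame(rows, columns=["feature", "n_replicates", "mean_rho", "sd_rho",
                                     "n_bins_used", "per_replicate_rho"])
    if len(df):
        df = df.sort_values(
            by=["mean_rho", "feature"],
            key=lambda col: -col.abs() if col.name == "mean_rho" else col,
            kind="stable",
        ).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def spearman_null_band(n_bins: int, alpha: float = 0.01, n_perm: int = 2000,
                       seed: int = 0) -> float:
    """Permutation null band for |rho| at the given bin count.

    Returns the (1−alpha) quantile of |Spearman rho| between a fixed rank
    vector and ``n_perm`` random permutations of it — the magnitude below
    which a correlation is indistinguishable from chance at that n.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    rng = np.random.default_rng(seed)
    base = np.arange(n_bins, dtype=float)
    base = (base - base.mean()) / base.std()
    perms = np.empty((n_perm, n_bins))
    for i in range(n_perm):
        perms[i] = rng.permutation(base)
    rhos = perms @ base / n_bins
    return float(np.quantile(np.abs(rhos), 1 - alpha))
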