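"""Fixed-width genomic binning and log2 treated/control enrichment tracks.

The central data products of a capture-sequencing map: fragment counts on a
fixed-width bin grid (default 50 kb), counts normalized to the total read
count of each library, and per-replicate ``log2(treated/control)`` enrichment
values per bin.  Coordinates are 0-based half-open throughout (BED
convention); a fragment is assigned to exactly one bin, the one containing
its midpoint, so count conservation is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BinGrid",
    "BinnedTrack",
    "make_bins",
    "count_fragments",
    "normalize_total",
    "log2_enrichment",
    "mask_bins",
    "mean_log2_track",
    "pooled_log2_track",
]

DEFAULT_BIN_WIDTH = 50_000
DEFAULT_PSEUDOCOUNT = 0.5
NORM_SCALE = 1e6


@dataclass(frozen=True)
class BinGrid:
    """A tiling of every chromosome by fixed-width bins.

    Bins tile each chromosome without gaps or overlaps; every bin has width
    ``bin_width`` except possibly the last bin of a chromosome, which is
    truncated at the chromosome end and flagged partial.  Global bin order is
    chromosome order as given in ``chrom_sizes``, then start coordinate.
    """

    chrom_sizes: tuple[tuple[str, int], ...]
    bin_width: int
    chroms: np.ndarray = field(repr=False)      # per-bin chromosome name
    starts: np.ndarray = field(repr=False)
    ends: np.ndarray = field(repr=False)
    partial: np.ndarray = field(repr=False)     # per-bin truncated-at-end flag
    offsets: dict = field(repr=False)           # chrom -> index of its first bin

    @property
    def n_bins(self) -> int:
        return self.starts.size

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chrom_sizes)[chrom]

    def bin_index(self, chrom: str, pos: np.ndarray | int) -> np.ndarray | int:
        """Global bin index of position(s) on ``chrom`` (0-based)."""
        return self.offsets[chrom] + np.asarray(pos) // self.bin_width

    def __eq__(self, other: object) -> bool:  # value semantics for grid checks
        if not isinstance(other, BinGrid):
            return NotImplemented
        return self.chrom_sizes == other.chrom_sizes and self.bin_width == other.bin_width

    def __hash__(self) -> int:
        return hash((self.chrom_sizes, self.bin_width))


@dataclass
class BinnedTrack:
    """One number per bin of a :class:`BinGrid`, plus a validity mask.

    ``kind`` records what the numbers are: ``raw_count`` (non-negative
    integers), ``normalized`` (counts scaled to sum to 1e6), ``log2_enrichment``
    or ``feature``.  ``mask`` is True on valid bins; masked bins stay in place
    so tracks on the same grid remain positionally aligned.
    """

    grid: BinGrid
    values: np.ndarray
    kind: str
    label: str = ""
    replicate_id: int | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"track has {self.values.size} values for a grid of {self.grid.n_bins} bins"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask length does not match value length")
        if self.kind == "raw_count":
            vals = self.values
            if np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer):
                raise ValueError("raw_count tracks must hold non-negative integers")

    def with_values(self, values: np.ndarray, kind: str) -> "BinnedTrack":
        return BinnedTrack(
            grid=self.grid, values=values, kind=kind, label=self.label,
            replicate_id=self.replicate_id, mask=self.mask.copy(),
        )


def make_bins(chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
              bin_width: int = DEFAULT_BIN_WIDTH) -> BinGrid:
    """Tile each chromosome with ``bin_width`` bins; last bin may be partial.

    Parameters
    ----------
    chrom_sizes
        Ordered mapping (or sequence of pairs) of chromosome name to length in
        bp.  The given order fixes the global bin order.
    bin_width
        Bin width in bp (the study's resolution is 50 kb).
    """
    items = tuple(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else tuple(chrom_sizes)
    if not items:
        raise ValueError("chrom_sizes is empty: at least one chromosome is required")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    for name, length in items:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    chroms, starts, ends, partial = [], [], [], []
    offsets: dict[str, int] = {}
    n_so_far = 0
    for name, length in items:
        offsets[name] = n_so_far
        bin_starts = np.arange(0, length, bin_width, dtype=np.int64)
        bin_ends = np.minimum(bin_starts + bin_width, length)
        chroms.extend([name] * bin_starts.size)
        starts.append(bin_starts)
        ends.append(bin_ends)
        partial.append(bin_ends - bin_starts != bin_width)
        n_so_far += bin_starts.size
    return BinGrid(
        chrom_sizes=items,
        bin_width=int(bin_width),
        chroms=np.asarray(chroms, dtype=object),
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        partial=np.concatenate(partial),
        offsets=offsets,
    )


def count_fragments(fragments, grid: BinGrid, *,
                    on_missing_chrom: str = "warn") -> BinnedTrack:
    """Count fragments per bin by the midpoint rule.

    Each fragment increments exactly one bin: the bin containing its midpoint
    ``floor((start + end) / 2)``.  With half-open bins a midpoint falling on a
    bin boundary belongs to the right-hand bin.  The total count equals the
    number of fragments on chromosomes shared with the grid.

    Parameters
    ----------
    fragments
        A :class:`~polkmap.simulate.FragmentSet` or any object with a
        ``by_chrom()`` method yielding ``(chrom, starts, ends)`` arrays.
    on_missing_chrom
        ``"warn"`` (default) skips fragments on chromosomes absent from the
        grid with a warning; ``"raise"`` rejects them.
    """
    if on_missing_chrom not in ("warn", "raise"):
        raise ValueError("on_missing_chrom must be 'warn' or 'raise'")
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom, starts, ends in fragments.by_chrom():
        if chrom not in grid.offsets:
            if on_missing_chrom == "raise":
                raise ValueError(f"fragment chromosome {chrom!r} is absent from the bin grid")
            warnings.warn(
                f"skipping {starts.size} fragments on {chrom!r}: not in the bin grid",
                stacklevel=2,
            )
            continue
        mid = (starts + ends) // 2
        idx = grid.bin_index(chrom, mid)
        counts += np.bincount(idx, minlength=grid.n_bins)
    label = getattr(fragments, "label", "")
    rep = getattr(fragments, "replicate_id", None)
    return BinnedTrack(grid=grid, values=counts, kind="raw_count", label=label, replicate_id=rep)


def normalize_total(track: BinnedTrack, scale: float = NORM_SCALE) -> BinnedTrack:
    """Scale a raw-count track so its values sum to ``scale`` (default 1e6).

    This is the "normalized to the total read count" step: values become
    counts-per-million when ``scale`` is 1e6, making libraries of different
    depth comparable.
    """
    total = track.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize a track with zero total count")
    out = track.values * (scale / total)
    return track.with_values(out, "normalized")


def log2_enrichment(treated: BinnedTrack, control: BinnedTrack,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT) -> BinnedTrack:
    """Per-bin ``log2((treated + pc) / (control + pc))`` on normalized tracks.

    The enrichment track of the capture assay: positive where the captured
    library is over-represented relative to the input/control library.  Both
    tracks must live on the same grid; the result's mask is the intersection
    of the input masks.  A pseudocount of 0 is only allowed when no control
    bin is zero.
    """
    if treated.grid != control.grid:
        raise ValueError("treated and control tracks are on different bin grids")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(control.values == 0):
        raise ValueError("control track has zero bins; a positive pseudocount is required")
    mask = treated.mask & control.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2((treated.values + pseudocount) / (control.values + pseudocount))
    return BinnedTrack(
        grid=treated.grid, values=vals, kind="log2_enrichment",
        label=treated.label, replicate_id=treated.replicate_id, mask=mask,
    )


def mask_bins(track: BinnedTrack, *,
              control_raw: BinnedTrack | None = None,
              min_control_raw: int = 0,
              blacklist: Iterable[tuple[str, int, int]] = (),
              exclude_partial: bool = False,
              blacklist_fraction: float = 0.5) -> BinnedTrack:
    """Return a copy of ``track`` with low-evidence bins masked out.

    Masks (never drops — grid alignment is preserved) bins whose control raw
    count is below ``min_control_raw``, bins flagged partial when
    ``exclude_partial`` is set, and bins overlapped >= ``blacklist_fraction``
    of their length by the union of ``blacklist`` intervals.
    """
    if min_control_raw < 0:
        raise ValueError("min_control_raw must be >= 0")
    grid = track.grid
    mask = track.mask.copy()
    if control_raw is not None:
        if control_raw.grid != grid:
            raise ValueError("control_raw track is on a different grid")
        mask &= control_raw.values >= min_control_raw
    if exclude_partial:
        mask &= ~grid.partial

    blacklist = list(blacklist)
    if blacklist:
        # union coverage of blacklist per bin, via the same exact-integral
        # machinery the feature module uses
        from .features import _union_coverage_per_bin

        cov_bp = _union_coverage_per_bin(blacklist, grid)
        bin_len = grid.ends - grid.starts
        mask &= cov_bp / bin_len < blacklist_fraction

    return replace(track, values=track.values.copy(), mask=mask)


def mean_log2_track(per_replicate: Sequence[BinnedTrack]) -> BinnedTrack:
    """Mean of per-replicate log2 enrichment tracks (the cross-replicate map).

    The displayed genome-wide map aggregates several biological replicates;
    the default aggregation is the bin-wise mean of the per-replicate log2
    tracks, on the intersection of their masks.
    """
    if not per_replicate:
        raise ValueError("need at least one replicate track")
    grid = per_replicate[0].grid
    for t in per_replicate[1:]:
        if t.grid != grid:
            raise ValueError("replicate tracks are on different grids")
    mask = np.logical_and.reduce([t.mask for t in per_replicate])
    vals = np.mean([t.values for t in per_replicate], axis=0)
    return BinnedTrack(grid=grid, values=vals, kind="log2_enrichment",
                       label="mean_log2", mask=mask)


def pooled_log2_track(treated_raw: Sequence[BinnedTrack], control_raw: BinnedTrack,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> BinnedTrack:
    """Alternative aggregation: sum treated raw counts, then one log2 track."""
    if not treated_raw:
        raise ValueError("need at least one treated raw-count track")
    grid = treated_raw[0].grid
    pooled = np.zeros(grid.n_bins, dtype=np.int64)
    for t in treated_raw:
        if t.grid != grid:
            raise ValueError("treated tracks are on different grids")
        if t.kind != "raw_count":
            raise ValueError("pooling operates on raw_count tracks")
        pooled += t.values
    pooled_track = BinnedTrack(grid=grid, values=pooled, kind="raw_count", label="pooled")
    return log2_enrichment(normalize_total(pooled_track),
                           normalize_total(control_raw), pseudocount)
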