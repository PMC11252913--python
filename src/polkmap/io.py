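"""Readers and writers for the pipeline's text formats.

chrom.sizes, BED3/6/12, bedGraph, FASTA and fragment BED files, all in
0-based half-open coordinates.  bedGraph values are written with shortest
round-trippable float formatting, so write→read reproduces values exactly.
Optional ingestion of coordinate-sorted paired-end alignments (SAM/BAM via
pysam) reconstructs fragment intervals from proper pairs; everything
downstream consumes fragment BED, so the core pipeline has no alignment
dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .binning import BinnedTrack

__all__ = [
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "write_bedgraph_steps",
    "read_fragments_bed",
    "write_fragments_bed",
    "read_fasta",
    "write_fasta",
    "fragments_from_alignments",
]

BED12_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "thickStart",
                 "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts"]


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column name<TAB>length file, preserving order."""
    out: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected name<TAB>length, got {line!r}")
        try:
            length = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer length {parts[1]!r}") from exc
        if length <= 0:
            raise ValueError(f"{path}:{ln}: non-positive chromosome length {length}")
        out[parts[0]] = length
    if not out:
        raise ValueError(f"{path}: no chromosomes found")
    return out


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_sizes.items():
            fh.write(f"{name}\t{length}\n")


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s or s.startswith("#") or s.startswith("track")
            or s.startswith("browser"))


def read_bed(path, expected_columns: int = 3) -> pd.DataFrame:
    """Parse a BED file into a DataFrame with 0-based half-open intervals.

    ``expected_columns`` is the minimum column count (3, 6 or 12); extra
    columns beyond 12 are ignored.  Track/browser/comment lines are skipped;
    malformed lines are rejected with their line number; zero-length or
    inverted intervals are errors.
    """
    if expected_columns not in (3, 6, 12):
        raise ValueError("expected_columns must be 3, 6 or 12")
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if _is_skippable(line):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < expected_columns:
            raise ValueError(
                f"{path}:{ln}: expected >= {expected_columns} columns, got {len(parts)}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
        if start < 0:
            raise ValueError(f"{path}:{ln}: negative start {start}")
        if start >= end:
            raise ValueError(
                f"{path}:{ln}: zero/negative-length interval [{start}, {end})")
        row = [parts[0], start, end]
        if expected_columns >= 6:
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{ln}: invalid strand {strand!r}")
            row += [name, score, strand]
        if expected_columns == 12:
            if len(parts) < 12:
                raise ValueError(f"{path}:{ln}: BED12 requires 12 columns")
            row += [int(parts[6]), int(parts[7]), parts[8], int(parts[9]),
                    parts[10], parts[11]]
        rows.append(row)
    cols = BED12_COLUMNS[:expected_columns]
    return pd.DataFrame(rows, columns=cols)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED DataFrame as plain TSV (no header, no track line)."""
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    """Parse a 4-column bedGraph into (chrom, start, end, value)."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if _is_skippable(line):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: bedGraph needs 4 columns, got {len(parts)}")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed bedGraph line") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _fmt(v: float) -> str:
    return repr(float(v))


def write_bedgraph_steps(steps: Iterable[tuple], path, merge_runs: bool = False) -> None:
    """Write (chrom, start, end, value) steps as bedGraph.

    With ``merge_runs`` adjacent steps with equal values are coalesced; the
    re-read track is identical either way.
    """
    with open(path, "w") as fh:
        prev = None
        for chrom, start, end, value in steps:
            if merge_runs and prev is not None and prev[0] == chrom \
                    and prev[2] == start and prev[3] == value:
                prev = (chrom, prev[1], end, value)
                continue
            if prev is not None:
                fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{_fmt(prev[3])}\n")
            prev = (chrom, start, end, value)
        if prev is not None:
            fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{_fmt(prev[3])}\n")


def write_bedgraph(track: BinnedTrack, path, merge_runs: bool = False) -> None:
    """Write a binned track as bedGraph; masked bins are omitted."""
    g = track.grid
    steps = ((g.chroms[i], int(g.starts[i]), int(g.ends[i]), float(track.values[i]))
             for i in range(g.n_bins) if track.mask[i])
    write_bedgraph_steps(steps, path, merge_runs=merge_runs)


def read_fragments_bed(path, condition: str, replicate_id: int):
    """Read a fragment BED3 file into a FragmentSet."""
    from .simulate import FragmentSet

    df = read_bed(path, expected_columns=3)
    return FragmentSet(condition=condition, replicate_id=replicate_id,
                       chroms=df["chrom"].to_numpy(dtype=object),
                       starts=df["start"].to_numpy(dtype=np.int64),
                       ends=df["end"].to_numpy(dtype=np.int64))


def write_fragments_bed(fragments, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in zip(fragments.chroms, fragments.starts, fragments.ends):
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def fragments_from_alignments(path, condition: str = "treated",
                              replicate_id: int = 1, min_mapq: int = 0):
    """Reconstruct fragment intervals from proper read pairs (SAM/BAM).

    Keeps primary, properly-paired alignments and takes each pair's insert as
    leftmost start to rightmost end, counted once (from the leftmost mate).
    """
    import pysam

    from .simulate import FragmentSet

    chroms, starts, ends = [], [], []
    with pysam.AlignmentFile(str(path)) as af:
        for read in af:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or not read.is_proper_pair or read.is_read2
                    or read.mapping_quality < min_mapq):
                continue
            tlen = read.template_length
            if tlen == 0:
                continue
            left = min(read.reference_start, read.next_reference_start)
            chroms.append(read.reference_name)
            starts.append(left)
            ends.append(left + abs(tlen))
    return FragmentSet(condition=condition, replicate_id=replicate_id,
                       chroms=np.asarray(chroms, dtype=object),
                       starts=np.asarray(starts, dtype=np.int64),
                       ends=np.asarray(ends, dtype=np.int64))
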