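"""End-to-end pipeline: count → normalize → enrich → mask → correlate → profile.

Drives the full downstream analysis from a YAML/dict configuration naming the
fragment files per (condition, replicate), the chromosome sizes, the feature
manifest and the profile anchor specs.  All outputs are plain text (bedGraph,
TSV) plus a JSON manifest carrying input checksums and parameters; reruns on
identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .binning import (BinnedTrack, count_fragments, log2_enrichment, make_bins,
                      mask_bins, mean_log2_track, normalize_total, pooled_log2_track)
from .features import (aggregate_coverage_fraction, aggregate_signal_mean,
                       correlate_replicates, correlation_report,
                       gc_fraction_from_sequences)
from .profiles import (anchors_from_genes, anchors_from_intervals, fine_coverage,
                       profile_around_anchors)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("polkmap")

VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    ``fragments`` maps each library to its BED3 path:
    ``{"treated": {1: path, ...}, "control": {1: path, ...}}``.
    ``features`` is a list of ``{name, path, mode}`` entries with mode one of
    coverage_fraction | signal_mean | gc_fraction; ``profiles`` a list of
    ``{label, anchors, which, flank, step}`` where ``anchors`` is a BED6/BED12
    path and ``which`` one of tss | tes | start | end.
    """

    chrom_sizes_path: str
    fragments: dict
    outdir: str
    bin_width: int = 50_000
    pseudocount: float = 0.5
    min_control_raw: int = 0
    exclude_partial: bool = False
    blacklist_path: str | None = None
    aggregate: str = "mean_of_log2"  # or "pooled_counts"
    features: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    profile_pseudocount: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        frags = {cond: {int(rep): p for rep, p in reps.items()}
                 for cond, reps in raw.pop("fragments").items()}
        return cls(fragments=frags, **raw)

    def validate(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.aggregate not in ("mean_of_log2", "pooled_counts"):
            raise ValueError(f"unknown aggregate mode {self.aggregate!r}")
        paths = [self.chrom_sizes_path]
        for cond in ("treated", "control"):
            reps = self.fragments.get(cond, {})
            if not reps:
                raise ValueError(f"no {cond} fragment files configured")
            if len(set(reps)) != len(reps):
                raise ValueError(f"duplicate replicate labels for {cond}")
            paths.extend(reps.values())
        if self.blacklist_path:
            paths.append(self.blacklist_path)
        for feat in self.features:
            if feat["mode"] not in ("coverage_fraction", "signal_mean", "gc_fraction"):
                raise ValueError(f"unknown aggregation mode {feat['mode']!r}")
            paths.append(feat["path"])
        for prof in self.profiles:
            if prof["which"].lower() not in ("tss", "tes", "start", "end"):
                raise ValueError(f"unknown profile anchor type {prof['which']!r}")
            paths.append(prof["anchors"])
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full downstream analysis; returns the output manifest dict.

    Stages: load inputs, bin counts per library, normalize, per-replicate
    log2(treated/control), masking, cross-replicate aggregation, feature
    correlation report, anchor profiles.  A single control is shared by all
    treated replicates; several controls are pooled by summed counts before
    normalization.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": VERSION, "parameters": {
        "bin_width": config.bin_width, "pseudocount": config.pseudocount,
        "min_control_raw": config.min_control_raw,
        "exclude_partial": config.exclude_partial,
        "aggregate": config.aggregate, "seed": config.seed,
    }, "inputs": {}, "outputs": {}}

    chrom_sizes = pio.read_chrom_sizes(config.chrom_sizes_path)
    manifest["inputs"][str(config.chrom_sizes_path)] = _sha256(config.chrom_sizes_path)
    grid = make_bins(chrom_sizes, config.bin_width)

    @_stage("count")
    def _count():
        libs = {}
        for cond, reps in config.fragments.items():
            for rep, path in sorted(reps.items()):
                fs = pio.read_fragments_bed(path, cond, rep)
                manifest["inputs"][str(path)] = _sha256(path)
                libs[(cond, rep)] = (fs, count_fragments(fs, grid))
                log.info("counted %d fragments for %s rep %d", fs.n_fragments, cond, rep)
        return libs

    libs = _count()

    @_stage("enrich")
    def _enrich():
        control_raws = [t for (c, _), (_, t) in sorted(libs.items()) if c == "control"]
        pooled_control = control_raws[0]
        if len(control_raws) > 1:
            pooled = np.sum([t.values for t in control_raws], axis=0)
            pooled_control = BinnedTrack(grid=grid, values=pooled, kind="raw_count",
                                         label="control_pooled")
        control_norm = normalize_total(pooled_control)
        per_rep = {}
        for (cond, rep), (_, raw) in sorted(libs.items()):
            if cond != "treated":
                continue
            enr = log2_enrichment(normalize_total(raw), control_norm, config.pseudocount)
            per_rep[rep] = enr
        return pooled_control, per_rep

    pooled_control, per_rep = _enrich()

    @_stage("mask")
    def _mask():
        blacklist = []
        if config.blacklist_path:
            bl = pio.read_bed(config.blacklist_path, expected_columns=3)
            blacklist = list(bl.itertuples(index=False, name=None))
        return {rep: mask_bins(t, control_raw=pooled_control,
                               min_control_raw=config.min_control_raw,
                               blacklist=blacklist,
                               exclude_partial=config.exclude_partial)
                for rep, t in per_rep.items()}

    masked = _mask()

    @_stage("write_tracks")
    def _write_tracks():
        out = {}
        for rep, t in sorted(masked.items()):
            p = outdir / f"enrichment_treated_rep{rep}.bedGraph"
            pio.write_bedgraph(t, p)
            out[f"enrichment_rep{rep}"] = p.name
        if config.aggregate == "pooled_counts":
            agg = pooled_log2_track(
                [raw for (c, _), (_, raw) in sorted(libs.items()) if c == "treated"],
                pooled_control, config.pseudocount)
            agg.mask &= next(iter(masked.values())).mask
        else:
            agg = mean_log2_track(list(masked.values()))
        p = outdir / "enrichment_aggregate.bedGraph"
        pio.write_bedgraph(agg, p)
        out["enrichment_aggregate"] = p.name
        # TSV matrix: bin coordinates + one column per replicate + aggregate
        df = pd.DataFrame({"chrom": grid.chroms, "start": grid.starts,
                           "end": grid.ends})
        for rep, t in sorted(masked.items()):
            df[f"rep{rep}"] = t.values
        df["aggregate"] = agg.values
        df["masked"] = ~agg.mask
        p = outdir / "enrichment_matrix.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        out["enrichment_matrix"] = p.name
        return out

    manifest["outputs"].update(_write_tracks())

    @_stage("correlate")
    def _correlate():
        if not config.features:
            return {}
        summaries = []
        for feat in config.features:
            manifest["inputs"][str(feat["path"])] = _sha256(feat["path"])
            if feat["mode"] == "coverage_fraction":
                iv = pio.read_bed(feat["path"], expected_columns=3)
                fv = aggregate_coverage_fraction(
                    iv.itertuples(index=False, name=None), grid, feat["name"])
            elif feat["mode"] == "signal_mean":
                sig = pio.read_bedgraph(feat["path"])
                fv = aggregate_signal_mean(
                    sig.itertuples(index=False, name=None), grid, feat["name"])
            else:
                seqs = pio.read_fasta(feat["path"])
                fv = gc_fraction_from_sequences(seqs, grid, feat["name"])
            summaries.append(correlate_replicates(list(masked.values()), fv))
        p = outdir / "correlations.tsv"
        correlation_report(summaries, p)
        return {"correlations": p.name}

    manifest["outputs"].update(_correlate())

    @_stage("profiles")
    def _profiles():
        if not config.profiles:
            return {}
        out = {}
        treated_sets = [fs for (c, _), (fs, _) in sorted(libs.items()) if c == "treated"]
        control_sets = [fs for (c, _), (fs, _) in sorted(libs.items()) if c == "control"]
        from .simulate import FragmentSet
        pool = lambda sets, cond: FragmentSet(
            condition=cond, replicate_id=0,
            chroms=np.concatenate([s.chroms for s in sets]),
            starts=np.concatenate([s.starts for s in sets]),
            ends=np.concatenate([s.ends for s in sets]))
        for prof in config.profiles:
            step = int(prof.get("step", 100))
            flank = int(prof.get("flank", 10_000))
            tcov = fine_coverage(pool(treated_sets, "treated"), chrom_sizes, step)
            ccov = fine_coverage(pool(control_sets, "control"), chrom_sizes, step)
            which = prof["which"].lower()
            manifest["inputs"][str(prof["anchors"])] = _sha256(prof["anchors"])
            if which in ("tss", "tes"):
                genes = pio.read_bed(prof["anchors"], expected_columns=12)
                anchors = anchors_from_genes(genes, which=which.upper())
            else:
                iv = pio.read_bed(prof["anchors"], expected_columns=6)
                anchors = anchors_from_intervals(iv, which=which, label=prof["label"])
            anchors.label = prof["label"]
            res = profile_around_anchors(tcov, ccov, anchors, flank,
                                         config.profile_pseudocount)
            p = outdir / f"profile_{prof['label']}.tsv"
            res.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
            out[f"profile_{prof['label']}"] = p.name
        return out

    manifest["outputs"].update(_profiles())

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
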