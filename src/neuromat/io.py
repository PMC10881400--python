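"""Plain-text readers and writers for the pipeline's standard formats.

All on-disk artifacts are plain text: BED / ENCODE narrowPeak for
intervals, TSV for matrices and metadata, CSV for fluorescence traces
(rows = frames, first column = time in seconds, one column per ROI),
JSON for truth bundles and run summaries, Newick for dendrograms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calcium import TraceSet
from .chromatin import GenomicInterval, PeakAtlas


class PeakParseError(ValueError):
    pass


def read_peaks(path, format: str = "bed") -> list[GenomicInterval]:
    """Read a BED or ENCODE narrowPeak file into validated intervals.

    Comment (#) and track/browser lines are skipped.  narrowPeak extra
    columns are accepted and ignored beyond the name field.  Malformed
    coordinates raise :class:`PeakParseError` citing file and line.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    out: list[GenomicInterval] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PeakParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise PeakParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise PeakParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else None
            out.append(GenomicInterval(chrom, start, end, name))
    return out


def write_peaks(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_atlas_bed(atlas: PeakAtlas, path) -> None:
    write_peaks(atlas.intervals, path)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene").to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_metadata_tsv(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample").to_csv(path, sep="\t")


def read_sample_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_lengths_tsv(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").rename_axis("gene").to_frame().to_csv(path, sep="\t")


def read_gene_lengths_tsv(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["length_bp"]


def write_traces_csv(traces: TraceSet, path) -> None:
    """Trace layout: rows = frames, first column time_s, then one ROI per column."""
    df = traces.F.T.copy()
    df.insert(0, "time_s", traces.time_s)
    df.to_csv(path, index=False)


def read_traces_csv(path, frame_rate_hz: float | None = None) -> TraceSet:
    df = pd.read_csv(path)
    time_s = df["time_s"].to_numpy(dtype=float)
    F = df.drop(columns="time_s").T
    F.columns = np.arange(F.shape[1])
    if frame_rate_hz is None:
        if len(time_s) < 2:
            raise ValueError("cannot infer frame rate from a single frame")
        frame_rate_hz = 1.0 / float(np.median(np.diff(time_s)))
    return TraceSet(time_s=time_s, F=F, frame_rate_hz=frame_rate_hz)


def write_motif_annotation_tsv(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def read_motif_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_models_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_models_tsv(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in sorted(obj)] if isinstance(obj, set) else [
            _jsonify(v) for v in obj
        ]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
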