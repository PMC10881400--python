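"""Peak-atlas construction and chromatin state-transition analysis.

A global peak atlas is built by removing blacklisted regions from the
contributing peak sets and transitively merging all remaining peaks
within 500 bp.  Per-peak fragment counts are depth-normalized to 10
million mapped fragments, differential peaks are clustered (Ward linkage
or redundancy-stopped k-means), peaks are annotated to genes (intragenic
assignment, otherwise nearest transcription start site), and per-peak
mark-presence patterns at the NPC and neuron stages are matched against
state-transition templates — most importantly the poised/bivalent state
(H3K4me3 + H3K27me3 in NPCs) resolving towards active chromatin
(H3K27ac gain, H3K27me3 loss) in neurons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy.cluster.hierarchy import fcluster, linkage

from . import trend as _trend
from .trend import DETable

TRANSITION_LABELS = ("bivalent_resolving", "active_gaining", "immature_open", "stable", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class PeakAtlas:
    """Sorted, merged genomic intervals with stable ids."""

    intervals: list[GenomicInterval]
    provenance: list[str] = field(default_factory=list)

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[GenomicInterval], provenance: Sequence[str] = ()
    ) -> "PeakAtlas":
        ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        named = [
            GenomicInterval(iv.chrom, iv.start, iv.end, f"peak_{i:05d}")
            for i, iv in enumerate(ordered)
        ]
        return cls(intervals=named, provenance=list(provenance))

    @property
    def ids(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, iv.name) for iv in self.intervals],
            columns=["chrom", "start", "end", "name"],
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class SignalMatrix:
    """Peak x sample normalized fragment counts."""

    normalized: pd.DataFrame
    raw_totals: pd.Series
    target: float = 1e7


@dataclass
class StateCall:
    """Per-peak mark presence at each stage plus the transition label."""

    presence: pd.DataFrame  # MultiIndex columns (stage, mark), boolean
    labels: pd.Series  # peak -> transition label
    thresholds: pd.Series  # mark -> presence threshold used


def _to_pyranges(intervals: Sequence[GenomicInterval]) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in intervals],
                "Start": [iv.start for iv in intervals],
                "End": [iv.end for iv in intervals],
            }
        )
    )


def build_peak_atlas(
    peak_sets: Sequence[Sequence[GenomicInterval]],
    blacklist: Sequence[GenomicInterval] = (),
    merge_distance: int = 500,
    provenance: Sequence[str] = (),
) -> PeakAtlas:
    """Blacklist-filter, pool and transitively merge peaks into an atlas.

    Peaks overlapping any blacklist interval are removed first; the
    remaining peaks from all sets are pooled and merged whenever their
    gap is <= ``merge_distance`` bp (500 by default), transitively.  Ids
    are assigned in genomic order.
    """
    pooled = [iv for peaks in peak_sets for iv in peaks]
    if not pooled:
        return PeakAtlas(intervals=[], provenance=list(provenance))
    if blacklist:
        gr = _to_pyranges(pooled)
        hits = gr.count_overlaps(_to_pyranges(blacklist), overlap_col="n_black")
        df = hits.df
        keep = df[df["n_black"] == 0]
        pooled = [
            GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
            for r in keep.itertuples()
        ]
        if not pooled:
            return PeakAtlas(intervals=[], provenance=list(provenance))
    merged = _to_pyranges(pooled).merge(slack=merge_distance).df
    intervals = [
        GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End))
        for r in merged.itertuples()
    ]
    return PeakAtlas.from_intervals(intervals, provenance=provenance)


def normalize_depth(
    raw: pd.DataFrame, totals: Mapping[str, float] | pd.Series, target: float = 1e7
) -> SignalMatrix:
    """Scale per-sample counts to a common sequencing depth.

    normalized[p, s] = raw[p, s] * target / total(s); default target is
    10 million mapped fragments.
    """
    totals = pd.Series(totals).reindex(raw.columns)
    if totals.isna().any():
        raise ValueError(f"missing totals for: {totals.index[totals.isna()].tolist()}")
    if (totals <= 0).any():
        raise ValueError(f"non-positive total for: {totals.index[totals <= 0].tolist()}")
    return SignalMatrix(normalized=raw * (target / totals), raw_totals=totals, target=target)


def cluster_differential_peaks(
    signal: SignalMatrix,
    de_peaks: Sequence[DETable],
    method: str = "ward",
    n_clusters: int | None = None,
    fdr_threshold: float = 0.05,
    kmeans_params: dict | None = None,
) -> pd.Series:
    """Cluster the union of differential peaks on z-scored signal rows.

    ``de_peaks`` are per-contrast differential tables over the atlas; the
    union of peaks at FDR <= ``fdr_threshold`` is clustered.  ``ward``
    performs agglomerative clustering with Ward linkage cut at
    ``n_clusters``; ``kmeans_redundancy`` delegates to
    :func:`neuromat.trajectory.kmeans_redundancy`.  Cluster ids are
    ordered by descending size (1 = largest).  Returns an empty Series
    (with a warning) when no peak is differential.
    """
    diff_ids: set[str] = set()
    for table in de_peaks:
        sig = table.table.index[table.table["fdr"] <= fdr_threshold]
        diff_ids.update(sig)
    diff_ids &= set(signal.normalized.index)
    if not diff_ids:
        warnings.warn("no differential peaks at the requested FDR; empty clustering")
        return pd.Series(dtype=int, name="cluster")
    X = signal.normalized.loc[sorted(diff_ids)]
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {(~keep).sum()} zero-variance peak(s) before clustering")
    Z = X.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    if method == "ward":
        if n_clusters is None:
            raise ValueError("ward mode needs n_clusters")
        lk = linkage(Z.to_numpy(), method="ward")
        raw = fcluster(lk, t=n_clusters, criterion="maxclust")
        assign = pd.Series(raw, index=Z.index)
    elif method == "kmeans_redundancy":
        from .trajectory import kmeans_redundancy

        params = dict(kmeans_params or {})
        res = kmeans_redundancy(Z, **params)
        assign = pd.Series(res.assignments + 1, index=Z.index)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    # relabel by descending cluster size, ties by original id
    order = assign.value_counts().sort_values(ascending=False).index
    remap = {old: new + 1 for new, old in enumerate(order)}
    out = assign.map(remap)
    out.name = "cluster"
    return out


def annotate_peaks_to_genes(atlas: PeakAtlas, genes: pd.DataFrame) -> pd.Series:
    """Assign each atlas peak to a gene.

    Intragenic peaks (overlapping a gene body) are assigned to that gene;
    when a peak overlaps several genes, the gene whose TSS is nearest to
    the peak midpoint wins (then lexicographic gene id).  Other peaks go
    to the nearest TSS on the same chromosome, measured from the peak
    midpoint.  Peaks on chromosomes without genes map to missing.

    ``genes`` needs columns gene_id, chrom, start, end, strand; the TSS
    is the strand-aware 5' end.
    """
    for col in ("gene_id", "chrom", "start", "end", "strand"):
        if col not in genes.columns:
            raise ValueError(f"gene models lack column {col!r}")
    bad = genes[genes["start"] >= genes["end"]]
    if len(bad):
        raise ValueError(f"invalid gene span(s): {bad['gene_id'].tolist()[:5]}")
    g = genes.copy()
    g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"])
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in g.groupby("chrom")}
    result = {}
    for iv in atlas.intervals:
        sub = by_chrom.get(iv.chrom)
        if sub is None:
            result[iv.name] = None
            continue
        mid = iv.midpoint
        overlapping = sub[(sub["start"] < iv.end) & (sub["end"] > iv.start)]
        candidates = overlapping if len(overlapping) else sub
        dist = (candidates["tss"] - mid).abs()
        best = candidates.loc[dist == dist.min(), "gene_id"].min()
        result[iv.name] = best
    out = pd.Series(result, name="gene_id")
    return out.reindex(atlas.ids)


def call_chromatin_states(
    signal: Mapping[tuple[str, str], pd.DataFrame] | Mapping[tuple[str, str], SignalMatrix],
    stages: Sequence[str] = ("NPC", "neuron"),
    marks: Sequence[str] = ("H3K4me3", "H3K27me3", "H3K27ac", "H3K9me3"),
    presence_factor: float = 2.0,
    thresholds: Mapping[str, float] | None = None,
) -> StateCall:
    """Call per-peak chromatin state transitions between two stages.

    ``signal`` maps (mark, stage) to a peak x replicate matrix of
    normalized counts (or a :class:`SignalMatrix`).  A mark is present at
    a peak/stage when its replicate-mean signal reaches the presence
    threshold — by default ``presence_factor`` (2x) times the atlas-wide
    median of that mark across both stages; explicit per-mark
    ``thresholds`` override this.  Presence patterns are matched against
    the transition templates:

    - bivalent_resolving: H3K4me3 and H3K27me3 in NPC; H3K27ac without
      H3K27me3 in neurons.
    - active_gaining: neither H3K4me3 nor H3K27ac in NPC; H3K4me3 and
      H3K27ac without H3K27me3 in neurons.
    - immature_open: H3K4me3 and H3K27ac in NPC; none of the active marks
      in neurons.
    - stable: identical presence pattern at both stages.
    - other: anything else.
    """
    first, second = stages
    mean_signal: dict[tuple[str, str], pd.Series] = {}
    for mark in marks:
        for stage in stages:
            if (mark, stage) not in signal:
                raise ValueError(f"missing signal for mark {mark!r} at stage {stage!r}")
            mat = signal[(mark, stage)]
            if isinstance(mat, SignalMatrix):
                mat = mat.normalized
            mean_signal[(mark, stage)] = mat.mean(axis=1)
    peaks = mean_signal[(marks[0], first)].index
    thr = {}
    for mark in marks:
        if thresholds is not None and mark in thresholds:
            thr[mark] = float(thresholds[mark])
        else:
            pooled = np.concatenate([mean_signal[(mark, s)].to_numpy() for s in stages])
            thr[mark] = presence_factor * float(np.median(pooled))
    presence = pd.DataFrame(
        {
            (stage, mark): mean_signal[(mark, stage)] >= thr[mark]
            for stage in stages
            for mark in marks
        }
    )
    presence.columns = pd.MultiIndex.from_tuples(presence.columns, names=["stage", "mark"])

    p1 = presence[first]
    p2 = presence[second]
    bivalent = (
        p1["H3K4me3"] & p1["H3K27me3"] & p2["H3K27ac"] & ~p2["H3K27me3"]
    )
    active_gain = (
        ~p1["H3K4me3"] & ~p1["H3K27ac"] & p2["H3K4me3"] & p2["H3K27ac"] & ~p2["H3K27me3"]
    )
    immature = (
        p1["H3K4me3"] & p1["H3K27ac"] & ~p2["H3K4me3"] & ~p2["H3K27ac"] & ~p2["H3K27me3"]
    )
    same = (p1.to_numpy() == p2.to_numpy()).all(axis=1)
    labels = pd.Series("other", index=peaks, dtype=object, name="transition")
    labels[same] = "stable"
    labels[immature] = "immature_open"
    labels[active_gain] = "active_gaining"
    labels[bivalent] = "bivalent_resolving"
    return StateCall(presence=presence, labels=labels, thresholds=pd.Series(thr, name="threshold"))


def intersect_expression_zscores(
    clusters: pd.Series,
    annotation: pd.Series,
    de_genes: Sequence[str],
    expr: pd.DataFrame,
) -> pd.DataFrame:
    """Mean expression z-score profile per peak cluster.

    Each gene's timepoint-mean expression (``expr``: gene x ordered
    timepoints) is z-scored across timepoints; per cluster the mean
    z-profile over its annotated, differentially expressed genes is
    reported.  Clusters without qualifying genes (or whose genes are all
    flat) are omitted with a warning.
    """
    de_set = set(de_genes)
    sd = expr.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"excluding {int(flat.sum())} flat gene(s) from z-scoring")
    z = expr.loc[~flat].sub(expr.loc[~flat].mean(axis=1), axis=0).div(sd[~flat], axis=0)
    rows = {}
    for cl in sorted(clusters.unique()):
        peaks = clusters.index[clusters == cl]
        genes = {
            annotation.get(p)
            for p in peaks
            if annotation.get(p) is not None and annotation.get(p) in de_set
        }
        genes = sorted(g for g in genes if g in z.index)
        if not genes:
            warnings.warn(f"cluster {cl} has no annotated differential genes")
            continue
        rows[cl] = z.loc[genes].mean(axis=0)
    return pd.DataFrame(rows).T.rename_axis("cluster")
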