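"""Hypergeometric motif enrichment with odds-ratio and expression filters.

For a group of peaks within a peak atlas, each motif's enrichment is the
upper-tail hypergeometric probability of observing at least the group's
motif-bearing peak count, given the motif's prevalence in the atlas.  The
odds ratio is the foreground ratio (motif-bearing fraction in the group)
over the background ratio (in the atlas).  Enriched motifs are then
filtered by odds ratio >= 1.2 and by the expression of an associated
transcription factor (>= 1 RPKM at any neuronal timepoint), so that only
motifs whose factor is actually expressed are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

NEURON_TIMEPOINTS = ("d25", "d50", "d75", "d100")


@dataclass
class MotifAnnotation:
    """Peak -> motif sets, with optional motif -> transcription factor map."""

    peak_motifs: dict[str, set[str]]
    motif_factors: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, motif_factors: Mapping[str, Sequence[str]] | None = None
    ) -> "MotifAnnotation":
        """Build from a (peak_id, motif_id) long-format table."""
        peak_motifs: dict[str, set[str]] = {}
        for peak, motif in zip(table["peak_id"], table["motif_id"]):
            peak_motifs.setdefault(peak, set()).add(motif)
        return cls(
            peak_motifs=peak_motifs,
            motif_factors={m: list(fs) for m, fs in (motif_factors or {}).items()},
        )

    @property
    def motifs(self) -> list[str]:
        return sorted({m for ms in self.peak_motifs.values() for m in ms})


def motif_enrichment(
    group: set[str] | Sequence[str],
    atlas: set[str] | Sequence[str],
    annot: MotifAnnotation,
    group_name: str = "group",
) -> pd.DataFrame:
    """Hypergeometric motif enrichment of a peak group against the atlas.

    For each motif with K carriers among the N atlas peaks and k carriers
    among the n group peaks: foreground_ratio = k/n, background_ratio =
    K/N, odds_ratio = foreground/background, and the p-value is the
    upper tail P(X >= k) of Hypergeometric(N, K, n).  FDR is
    Benjamini-Hochberg across motifs within the group.
    """
    group = set(group)
    atlas = set(atlas)
    if not group:
        raise ValueError("group is empty")
    stray = group - atlas
    if stray:
        raise ValueError(f"group peaks outside the atlas: {sorted(stray)[:10]}")
    n, N = len(group), len(atlas)
    rows = []
    for motif in annot.motifs:
        carriers = {p for p, ms in annot.peak_motifs.items() if motif in ms and p in atlas}
        K = len(carriers)
        k = len(carriers & group)
        fg = k / n
        bg = K / N
        odds = fg / bg if bg > 0 else (np.inf if fg > 0 else 0.0)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((group_name, motif, k, K, fg, bg, odds, p))
    res = pd.DataFrame(
        rows,
        columns=[
            "group", "motif", "k", "K",
            "foreground_ratio", "background_ratio", "odds_ratio", "pvalue",
        ],
    )
    if len(res):
        _, fdr, _, _ = multipletests(res["pvalue"], method="fdr_bh")
        res["fdr"] = fdr
    else:
        res["fdr"] = pd.Series(dtype=float)
    return res.set_index("motif")


def filter_enriched_motifs(
    res: pd.DataFrame,
    tf_rpkm: pd.DataFrame,
    motif_factors: Mapping[str, Sequence[str]],
    or_min: float = 1.2,
    rpkm_min: float = 1.0,
    neuron_timepoints: Sequence[str] = NEURON_TIMEPOINTS,
    return_all: bool = False,
) -> pd.DataFrame:
    """Filter enriched motifs by odds ratio and factor expression.

    Keeps motifs with odds_ratio >= ``or_min`` (inclusive) whose
    associated transcription factor reaches ``rpkm_min`` RPKM at any
    neuronal timepoint.  Motifs without a mapped factor in ``tf_rpkm``
    are dropped with a warning.  The result is ranked by descending odds
    ratio, then ascending p-value, then motif id, and carries a
    ``pass_filter`` flag alongside the surviving rows.
    """
    tps = [t for t in neuron_timepoints if t in tf_rpkm.columns]
    if not tps:
        raise ValueError("tf_rpkm has no neuronal timepoint columns")
    keep_rows = []
    for motif, row in res.iterrows():
        factors = [f for f in motif_factors.get(motif, []) if f in tf_rpkm.index]
        if not factors:
            warnings.warn(f"motif {motif} has no mapped factor with expression data; dropped")
            continue
        max_rpkm = float(tf_rpkm.loc[factors, tps].max().max())
        passed = row["odds_ratio"] >= or_min and max_rpkm >= rpkm_min
        keep_rows.append((motif, row["odds_ratio"], row["pvalue"], max_rpkm, passed))
    out = pd.DataFrame(
        keep_rows, columns=["motif", "odds_ratio", "pvalue", "max_neuron_rpkm", "pass_filter"]
    )
    out = out.sort_values(
        by=["odds_ratio", "pvalue", "motif"], ascending=[False, True, True], kind="stable"
    ).set_index("motif")
    merged = res.loc[out.index].copy()
    merged["max_neuron_rpkm"] = out["max_neuron_rpkm"].astype(float)
    merged["pass_filter"] = out["pass_filter"].astype(bool)
    if return_all:
        return merged
    return merged[merged["pass_filter"]].drop(columns="pass_filter")
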