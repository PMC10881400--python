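"""Expression preprocessing and monotonic transcript-trend classification.

The maturation time course is staged by classifying each transcript's
behaviour over the neuronal timepoints d25 -> d50 -> d75 -> d100 into
monotonically up- or down-regulated trends.  A trend call is a boolean
combination of per-comparison log2 fold changes and Benjamini-Hochberg
FDR values from the four pairwise contrasts d50 vs d25, d75 vs d50,
d100 vs d50 and d100 vs d25:

``strict`` calls require every transition to pass the significance
threshold (FDR <= 0.05 inclusive), positive (negative) fold change at the
d50 vs d25 and d75 vs d50 transitions, and an overall d100 vs d25 fold
change exceeding (below) the d50 vs d25 fold change.  ``relaxed`` calls
require only the d100 vs d25 transition to be significant together with a
consistent early fold change and either a consistent overall or
intermediate fold change.  Strict calls are a subset of relaxed calls by
construction.

Counts are made comparable across replicates by RPKM transformation, and
a gene is considered present when it reaches 1 RPKM in at least one
sample.  The differential test used here is a deliberately simple
stand-in (Welch's t on log2(RPKM+1) with BH correction); externally
produced tables with the same columns can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: The four pairwise contrasts the monotonic rules are written over.
COMPARISONS = ("d50_vs_d25", "d75_vs_d50", "d100_vs_d50", "d100_vs_d25")

#: Neuronal timepoints (post-neurogenesis); the trend rules apply to these.
NEURON_TIMEPOINTS = ("d25", "d50", "d75", "d100")

TREND_CATEGORIES = (
    "mono_up_strict",
    "mono_up_relaxed",
    "mono_down_strict",
    "mono_down_relaxed",
    "none",
)


@dataclass
class ExpressionTimecourse:
    """Gene x sample count matrix with sample metadata and gene lengths.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes as rows, samples as columns.
    gene_lengths
        Transcript length in bp per gene (index aligned with ``counts``).
    samples
        Per-sample metadata with columns ``timepoint``, ``treatment`` and
        ``replicate``, indexed by sample name.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = set(self.counts.columns) - set(self.samples.index)
        if missing_meta:
            raise ValueError(f"samples without metadata: {sorted(missing_meta)}")
        for col in ("timepoint", "treatment", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any():
            bad = lengths.index[lengths.isna()][:5].tolist()
            raise ValueError(f"genes without length: {bad}")
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0][:5].tolist()
            raise ValueError(f"non-positive gene length for: {bad}")
        self.gene_lengths = lengths

    def select_samples(self, timepoint: str | None = None, treatment: str | None = None) -> list[str]:
        """Sample names matching the given timepoint and/or treatment."""
        mask = pd.Series(True, index=self.samples.index)
        if timepoint is not None:
            mask &= self.samples["timepoint"] == timepoint
        if treatment is not None:
            mask &= self.samples["treatment"] == treatment
        return [s for s in self.counts.columns if mask.get(s, False)]


@dataclass
class DETable:
    """Per-gene differential-expression result for one pairwise comparison.

    ``table`` has columns ``logFC`` (log2), ``pvalue`` and ``fdr``
    (Benjamini-Hochberg), indexed by gene.
    """

    comparison: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for col in ("logFC", "pvalue", "fdr"):
            if col not in self.table.columns:
                raise ValueError(f"DETable lacks column {col!r}")
        fdr = self.table["fdr"]
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValueError("fdr outside [0, 1]")


def compute_rpkm(tc: ExpressionTimecourse) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM[g, s] = counts[g, s] / (length_kb(g) * total_counts(s) / 1e6).
    """
    totals = tc.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {zero.index.tolist()}")
    length_kb = tc.gene_lengths / 1e3
    per_million = totals / 1e6
    return tc.counts.div(length_kb, axis=0).div(per_million, axis=1)


def presence_filter(rpkm: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes present (>= ``threshold`` RPKM) in at least one sample.

    The default of 1 RPKM defines transcript presence; gene order is
    preserved.
    """
    if threshold < 0:
        raise ValueError(f"presence threshold must be >= 0, got {threshold}")
    if not np.isfinite(rpkm.to_numpy()).all():
        raise ValueError("rpkm matrix contains non-finite values")
    keep = (rpkm >= threshold).any(axis=1)
    return rpkm.index[keep]


def naive_differential(
    tc: ExpressionTimecourse,
    group_a: Sequence[str],
    group_b: Sequence[str],
    comparison: str = "A_vs_B",
    rpkm: pd.DataFrame | None = None,
) -> DETable:
    """Simple two-group differential test on log2(RPKM + 1).

    logFC is the difference of group means (A minus B), the p-value comes
    from Welch's unequal-variance t-test, and FDR is Benjamini-Hochberg
    across all tested genes.  Genes with zero variance in both groups and
    equal means get p = 1.  This is a transparent stand-in for a
    count-model differential test; externally produced tables can be used
    wherever a :class:`DETable` is accepted.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if rpkm is None:
        rpkm = compute_rpkm(tc)
    log_a = np.log2(rpkm[group_a].to_numpy() + 1.0)
    log_b = np.log2(rpkm[group_b].to_numpy() + 1.0)
    logfc = log_a.mean(axis=1) - log_b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    # Degenerate genes: no variance anywhere.  Equal means -> no evidence.
    degenerate = np.isnan(pvals)
    pvals = np.where(degenerate & (logfc == 0), 1.0, pvals)
    pvals = np.where(np.isnan(pvals), 0.0, pvals)  # zero variance, unequal means
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame({"logFC": logfc, "pvalue": pvals, "fdr": fdr}, index=rpkm.index)
    return DETable(comparison=comparison, table=table)


def _aligned(de: Mapping[str, DETable]) -> tuple[pd.Index, dict[str, pd.DataFrame]]:
    missing = [c for c in COMPARISONS if c not in de]
    if missing:
        raise ValueError(f"missing comparison table(s): {missing}")
    genes = de[COMPARISONS[0]].table.index
    for c in COMPARISONS[1:]:
        genes = genes.intersection(de[c].table.index)
    dropped = set(de[COMPARISONS[0]].table.index) - set(genes)
    if dropped:
        logger.debug("genes absent from some comparison labelled none: %d", len(dropped))
    tables = {c: de[c].table.reindex(genes) for c in COMPARISONS}
    return genes, tables


def classify_monotonic(
    de: Mapping[str, DETable],
    direction: str,
    mode: str,
    fdr_threshold: float = 0.05,
) -> pd.Series:
    """Apply the printed monotonic-trend rules gene by gene.

    Parameters
    ----------
    de
        Mapping from comparison name (:data:`COMPARISONS`) to its table.
    direction
        ``"up"`` or ``"down"``.
    mode
        ``"strict"`` (every transition significant) or ``"relaxed"``.
    fdr_threshold
        Significance threshold, inclusive (FDR <= threshold).

    Returns
    -------
    Boolean Series over the common gene universe; genes missing from any
    required table are excluded (labelled not-called by the callers).
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"mode must be 'strict' or 'relaxed', got {mode!r}")
    genes, t = _aligned(de)
    fc = {c: t[c]["logFC"] for c in COMPARISONS}
    sig = {c: t[c]["fdr"] <= fdr_threshold for c in COMPARISONS}

    if direction == "up":
        if mode == "strict":
            call = (
                sig["d50_vs_d25"]
                & sig["d100_vs_d25"]
                & sig["d100_vs_d50"]
                & (fc["d50_vs_d25"] > 0)
                & (fc["d75_vs_d50"] > 0)
                & (fc["d100_vs_d25"] > fc["d50_vs_d25"])
            )
        else:
            call = (
                sig["d100_vs_d25"]
                & (fc["d50_vs_d25"] > 0)
                & ((fc["d100_vs_d25"] >= fc["d50_vs_d25"]) | (fc["d75_vs_d50"] > 0))
            )
    else:
        if mode == "strict":
            call = (
                sig["d50_vs_d25"]
                & sig["d100_vs_d25"]
                & sig["d100_vs_d50"]
                & (fc["d50_vs_d25"] < 0)
                & (fc["d75_vs_d50"] < 0)
                & (fc["d100_vs_d25"] < fc["d50_vs_d25"])
            )
        else:
            call = (
                sig["d100_vs_d25"]
                & (fc["d50_vs_d25"] < 0)
                & ((fc["d100_vs_d25"] <= fc["d50_vs_d25"]) | (fc["d75_vs_d50"] < 0))
            )
    call = call.fillna(False)
    call.name = f"mono_{direction}_{mode}"
    return call


def trend_labels(de: Mapping[str, DETable], fdr_threshold: float = 0.05) -> pd.Series:
    """Combined per-gene trend label over the full gene universe.

    Strict labels take precedence over relaxed; up and down are mutually
    exclusive (they require opposite d50 vs d25 fold-change signs).  Genes
    absent from any comparison table are labelled ``none``.
    """
    universe = de[COMPARISONS[0]].table.index
    for c in COMPARISONS[1:]:
        if c in de:
            universe = universe.union(de[c].table.index)
    labels = pd.Series("none", index=universe, dtype=object)
    calls = {
        (d, m): classify_monotonic(de, d, m, fdr_threshold)
        for d in ("up", "down")
        for m in ("strict", "relaxed")
    }
    for d in ("up", "down"):
        relaxed = calls[(d, "relaxed")]
        strict = calls[(d, "strict")]
        labels.loc[relaxed.index[relaxed]] = f"mono_{d}_relaxed"
        labels.loc[strict.index[strict]] = f"mono_{d}_strict"
    labels.name = "trend"
    return labels


def select_marker_genes(
    labels: pd.Series,
    rpkm: pd.DataFrame,
    de: Mapping[str, DETable],
    sem_d100: pd.Series,
    timepoint_of: Mapping[str, str] | pd.Series | None = None,
    max_abs_logfc: float = 1.0,
    min_peak_rpkm: float = 5.0,
    max_sem: float = 1.0,
) -> list[str]:
    """Marker-gene selection among trend-labelled genes.

    Retains labelled genes whose maximum |logFC| over the four comparisons
    exceeds ``max_abs_logfc``, whose maximum timepoint-mean RPKM exceeds
    ``min_peak_rpkm``, and whose d100 standard error of the mean is
    strictly below ``max_sem``.

    ``timepoint_of`` maps sample name to timepoint; when omitted each RPKM
    column is treated as its own timepoint.
    """
    labelled = [g for g in labels.index if labels[g] != "none"]
    missing_sem = [g for g in labelled if g not in sem_d100.index]
    if missing_sem:
        raise ValueError(f"missing sem_d100 entries for: {missing_sem[:5]}")
    if timepoint_of is not None:
        tp = pd.Series(timepoint_of)
        tp_mean = rpkm.T.groupby(tp.reindex(rpkm.columns)).mean().T
    else:
        tp_mean = rpkm
    _, tables = _aligned(de)
    abs_fc = pd.concat([tables[c]["logFC"].abs() for c in COMPARISONS], axis=1).max(axis=1)
    out = []
    for g in labelled:
        if g not in abs_fc.index or g not in tp_mean.index:
            continue
        if (
            abs_fc[g] > max_abs_logfc
            and tp_mean.loc[g].max() > min_peak_rpkm
            and sem_d100[g] < max_sem
        ):
            out.append(g)
    return out


def write_labels_tsv(labels: pd.Series, path) -> None:
    labels.rename_axis("gene").to_frame().to_csv(path, sep="\t")


def read_de_table_tsv(path) -> dict[str, DETable]:
    """Read external DE tables (columns gene, comparison, logFC, pvalue, fdr)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "comparison", "logFC", "pvalue", "fdr"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    out = {}
    for comp, sub in df.groupby("comparison"):
        out[comp] = DETable(comparison=comp, table=sub.set_index("gene")[["logFC", "pvalue", "fdr"]])
    return out
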