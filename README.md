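# neuromat

Staging the maturation of human cortical neurons from multi-omic time
courses.

Human pluripotent stem-cell (hPSC)-derived cortical neurons mature over
months, and that slow unfolding can be staged quantitatively: bulk
RNA-seq time courses yield monotonically up- or down-regulated
transcript programmes, PCA of the expression samples defines a
maturation trajectory along which treatments can be scored, calcium
imaging quantifies the emergence of spontaneous and synchronous network
activity, and CUT&RUN/ATAC peak atlases reveal bivalent (H3K4me3 +
H3K27me3) chromatin in neural precursors resolving towards active
chromatin (H3K27ac gain, H3K27me3 loss) in neurons. `neuromat`
implements this analysis battery as a tested, reusable pipeline, with
simulators that generate every input with planted ground truth so the
whole chain is verifiable without any external data.

## The core procedures

**Monotonic trend classification.** For the neuronal timepoints d25,
d50, d75, d100 and pairwise differential tables (log2 fold change,
Benjamini–Hochberg FDR), a transcript is *monotonically upregulated
(strict)* iff

    FDR(d50v25) <= 0.05  and  FDR(d100v25) <= 0.05  and  FDR(d100v50) <= 0.05
    and  logFC(d50v25) > 0  and  logFC(d75v50) > 0
    and  logFC(d100v25) > logFC(d50v25)

and *(relaxed)* iff

    FDR(d100v25) <= 0.05  and  logFC(d50v25) > 0
    and  ( logFC(d100v25) >= logFC(d50v25)  or  logFC(d75v50) > 0 )

with sign-mirrored rules for downregulation. Strict calls are a subset
of relaxed calls, and up/down are mutually exclusive. Counts are
RPKM-transformed; genes reaching 1 RPKM in at least one sample are
retained. Marker genes additionally satisfy max |logFC| > 1,
peak expression > 5 RPKM, and s.e.m. at d100 < 1.

**Maturation score.** Samples are embedded in PC1–3 of
variance-stabilized counts (top 1000 genes). With condition centroids
`c(t, d)` (mean over replicates), the origin at the control d25
centroid and the control vector `v = c(ctrl, d50) − c(ctrl, d25)`, a
condition's score is the dot product

    score(t, d) = (c(t, d) − c(ctrl, d25)) · v

so score(origin) = 0, score(control) = ‖v‖², and conditions advanced
along the chronological trajectory score higher.

**Calcium activity.** ΔF/F0 = (F − F0)/F0 with a running-percentile
baseline; spikes are thresholded local maxima of the (lightly smoothed)
ΔF/F0 trace with a refractory period; per-neuron amplitude is the mean
ΔF/F0 of detected spikes and frequency is spikes/min; the synchronous
firing rate counts windows in which ≥ 80% (configurable up to "all
ROIs") of neurons fire together, per minute of recording. The
NMDA/AMPA ratio divides the +40 mV current 20 ms after mEPSC onset by
the peak −70 mV current.

**Chromatin states.** A global peak atlas is built by removing
blacklisted regions and transitively merging peaks within 500 bp;
fragment counts are depth-normalized to 10 million fragments; per-peak
mark presence at the NPC and neuron stages is matched against
transition templates — most importantly *bivalent resolving*: H3K4me3 ∧
H3K27me3 in NPC, H3K27ac ∧ ¬H3K27me3 in neurons. Peaks annotate to
genes intragenically, otherwise by nearest TSS.

**Motif enrichment.** For a peak group (size n, k motif carriers)
against the atlas (size N, K carriers): foreground ratio k/n,
background ratio K/N, odds ratio = foreground/background, p-value =
upper-tail hypergeometric P(X ≥ k), BH-corrected per group; enriched
motifs are kept when the odds ratio ≥ 1.2 and an associated
transcription factor reaches ≥ 1 RPKM at any neuronal timepoint.

## Worked example

Run the full synthetic study (six-timepoint expression time course with
planted monotonic genes, ROI traces with planted spikes and network
events, a two-stage chromatin landscape with planted states, and motif
annotations with planted enrichment):

```
neuromat run-all --outdir out --seed 4
```

`out/summary.json` then contains (abridged):

```json
{
 "trend":     {"n_present": 2000, "n_called": 366, "recall": 0.9025, "fdr": 0.0137},
 "trajectory":{"scores": {"DMSO_d25": 0.0, "DMSO_d50": 411.05, "DMSO_d75": 802.15,
                          "DMSO_d100": 1201.03}},
 "calcium":   {"spike_recall": 0.914, "spike_fdr": 0.0,
               "sync_rate_per_min": 2.0, "planted_sync_rate_per_min": 2.0},
 "chromatin": {"bivalent_recovery": 0.998, "state_accuracy": 0.994,
               "bivalent_monoup_hypergeom_p": 4.4e-134},
 "enrich":    {"n_hits": 5, "planted_recall": 1.0}
}
```

Reading this: 366 of 2000 genes were called monotonic, recovering 90%
of the 400 planted trend genes at an empirical FDR of 1.4%; the
maturation score increases monotonically along the DMSO time course
(d25 = 0 by construction, d50 = ‖control vector‖²); the spike detector
recovered 91% of planted calcium events with no false calls and the
synchronous rate matched the planted network-event rate exactly; 99.8%
of planted bivalent-resolving peaks were labelled correctly and their
annotated genes coincide with the planted monotonically upregulated
genes far beyond chance (hypergeometric p ≈ 1e-134); all 5 planted
motifs passed the enrichment filter.

Individual stages are available as `neuromat simulate / trends / score /
calcium / chromatin / enrich`, and as library functions
(`neuromat.trend.classify_monotonic`,
`neuromat.trajectory.maturation_score`,
`neuromat.calcium.synchronous_firing_rate`,
`neuromat.chromatin.call_chromatin_states`,
`neuromat.enrich.motif_enrichment`, ...).

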