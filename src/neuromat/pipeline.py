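"""End-to-end synthetic study: configuration and stage orchestration.

:func:`run_pipeline` chains simulate -> trend -> trajectory -> calcium ->
chromatin -> enrich on synthetic data, writes every intermediate artifact
as plain text next to a machine-readable ``summary.json``, and records
the resolved configuration.  Stage seeds are derived deterministically
from the master seed, so a fixed seed yields byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from . import chromatin as ch
from . import enrich as en
from . import io as nio
from . import synthdata as sd
from . import trajectory as tj
from . import trend as tr

logger = logging.getLogger(__name__)


@dataclass
class StageToggles:
    expression: bool = True
    trajectory: bool = True
    calcium: bool = True
    chromatin: bool = True
    enrich: bool = True


@dataclass
class PipelineConfig:
    """Declarative configuration of the full synthetic study.

    Unknown keys are rejected on load; the resolved configuration is
    written next to the outputs of every run.
    """

    seed: int = 0
    stages: StageToggles = field(default_factory=StageToggles)
    expression: sd.SimExprConfig = field(default_factory=sd.SimExprConfig)
    calcium: sd.SimCalciumConfig = field(default_factory=sd.SimCalciumConfig)
    chromatin: sd.SimChromatinConfig = field(default_factory=sd.SimChromatinConfig)
    fdr_threshold: float = 0.05
    pca_top_n: int = 1000
    spike_threshold_sd: float = 3.0
    spike_min_amplitude: float = 0.2
    spike_refractory_s: float = 1.0
    sync_window_s: float = 0.5
    sync_participation: float = 0.8
    n_motifs: int = 20
    n_planted_motifs: int = 5
    motif_background_rate: float = 0.2
    motif_enrichment_factor: float = 2.5
    odds_ratio_min: float = 1.2
    tf_rpkm_min: float = 1.0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _build_dataclass(cls, raw, path="config")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_dataclass(cls, raw: dict, path: str):
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        ftype = fields[name].type
        target = {
            "StageToggles": StageToggles,
            "sd.SimExprConfig": sd.SimExprConfig,
            "sd.SimCalciumConfig": sd.SimCalciumConfig,
            "sd.SimChromatinConfig": sd.SimChromatinConfig,
        }.get(ftype if isinstance(ftype, str) else getattr(ftype, "__name__", ""))
        if target is None and dataclasses.is_dataclass(ftype):
            target = ftype
        if target is not None and isinstance(value, dict):
            kwargs[name] = _build_dataclass(target, value, path=f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ("expression", "calcium", "chromatin", "genes", "motifs")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _match_events(detected: np.ndarray, truth: np.ndarray, tol_s: float) -> int:
    """Count greedily matched (detected, truth) event pairs within tol_s."""
    truth = list(truth)
    matched = 0
    for t in detected:
        if not truth:
            break
        j = int(np.argmin([abs(t - u) for u in truth]))
        if abs(t - truth[j]) <= tol_s:
            truth.pop(j)
            matched += 1
    return matched


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the toggled stages end to end; returns the summary dict.

    Writes all artifacts plus ``summary.json`` and the resolved
    ``config.yaml`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed}
    timings: dict[str, float] = {}

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    tc = truth_expr = labels = rpkm = None
    if config.stages.expression or config.stages.trajectory or config.stages.chromatin:
        t0 = time.perf_counter()
        expr_cfg = dataclasses.replace(config.expression, seed=seeds["expression"])
        tc, truth_expr = sd.simulate_expression_timecourse(expr_cfg)
        nio.write_counts_tsv(tc.counts, outdir / "counts.tsv")
        nio.write_sample_metadata_tsv(tc.samples, outdir / "samples.tsv")
        nio.write_gene_lengths_tsv(tc.gene_lengths, outdir / "gene_lengths.tsv")
        rpkm = tr.compute_rpkm(tc)
        timings["simulate_expression"] = time.perf_counter() - t0

    if config.stages.expression:
        t0 = time.perf_counter()
        present = tr.presence_filter(rpkm, threshold=1.0)
        contrasts = {
            "d50_vs_d25": ("d50", "d25"),
            "d75_vs_d50": ("d75", "d50"),
            "d100_vs_d50": ("d100", "d50"),
            "d100_vs_d25": ("d100", "d25"),
        }
        rpkm_present = rpkm.loc[present]
        de = {}
        for name, (a, b) in contrasts.items():
            de[name] = tr.naive_differential(
                tc,
                tc.select_samples(timepoint=a, treatment="DMSO"),
                tc.select_samples(timepoint=b, treatment="DMSO"),
                comparison=name,
                rpkm=rpkm_present,
            )
        labels = tr.trend_labels(de, fdr_threshold=config.fdr_threshold)
        tr.write_labels_tsv(labels, outdir / "trend_labels.tsv")
        truth_lab = truth_expr.gene_trend_labels.reindex(labels.index).fillna("none")
        called_up = labels.str.startswith("mono_up")
        called_down = labels.str.startswith("mono_down")
        true_up = truth_lab == "mono_up"
        true_down = truth_lab == "mono_down"
        n_true = int(true_up.sum() + true_down.sum())
        n_called = int(called_up.sum() + called_down.sum())
        n_correct = int((called_up & true_up).sum() + (called_down & true_down).sum())
        summary["trend"] = {
            "n_present": int(len(present)),
            "n_called": n_called,
            "recall": n_correct / n_true if n_true else float("nan"),
            "fdr": (n_called - n_correct) / n_called if n_called else 0.0,
            "n_strict": int(labels.str.endswith("strict").sum()),
        }
        timings["trend"] = time.perf_counter() - t0

    if config.stages.trajectory:
        t0 = time.perf_counter()
        vst = tj.variance_stabilize(tc.counts)
        emb = tj.embed_pca(vst, top_n=min(config.pca_top_n, vst.shape[0]))
        cents = tj.condition_centroids(emb, tc.samples)
        scores = tj.maturation_score(cents, ("DMSO", "d25"), ("DMSO", "d50"))
        score_rows = [
            {"treatment": s.condition[0], "timepoint": s.condition[1],
             "PC1": s.vector[0], "PC2": s.vector[1], "PC3": s.vector[2], "score": s.score}
            for s in scores
        ]
        pd.DataFrame(score_rows).to_csv(outdir / "maturation_scores.tsv", sep="\t", index=False)
        lk, leaves = tj.correlation_cluster(vst)
        (outdir / "dendrogram.nwk").write_text(tj.linkage_to_newick(lk, leaves) + "\n")
        summary["trajectory"] = {
            "explained_variance": [round(float(v), 6) for v in emb.explained_variance],
            "scores": {
                f"{s.condition[0]}_{s.condition[1]}": round(float(s.score), 6) for s in scores
            },
            "leaf_order": leaves,
        }
        timings["trajectory"] = time.perf_counter() - t0

    if config.stages.calcium:
        t0 = time.perf_counter()
        ca_cfg = dataclasses.replace(config.calcium, seed=seeds["calcium"])
        traces, truth_ca = sd.simulate_calcium_traces(ca_cfg)
        nio.write_traces_csv(traces, outdir / "traces.csv")
        dff = ca.compute_dff(traces)
        spikes = ca.detect_spikes(
            dff,
            traces.frame_rate_hz,
            threshold_sd=config.spike_threshold_sd,
            min_amplitude=config.spike_min_amplitude,
            refractory_s=config.spike_refractory_s,
        )
        stats = ca.spike_statistics(spikes)
        stats.to_csv(outdir / "spike_stats.tsv", sep="\t")
        sync = ca.synchronous_firing_rate(
            spikes, window_s=config.sync_window_s, participation=config.sync_participation
        )
        tol = 2.0 / traces.frame_rate_hz
        n_det = n_match = n_true = 0
        for roi, ev in spikes.events.items():
            det = ev["time_s"].to_numpy()
            tru = truth_ca.spike_times[roi]
            n_det += len(det)
            n_true += len(tru)
            n_match += _match_events(det, tru, tol)
        planted_sync = 60.0 * len(truth_ca.sync_event_times) / ca_cfg.duration_s
        summary["calcium"] = {
            "spike_recall": n_match / n_true if n_true else float("nan"),
            "spike_fdr": (n_det - n_match) / n_det if n_det else 0.0,
            "mean_amplitude": round(float(stats["amplitude"].mean()), 6),
            "mean_frequency_per_min": round(float(stats["frequency_per_min"].mean()), 6),
            "sync_rate_per_min": round(float(sync.rate_per_min), 6),
            "planted_sync_rate_per_min": round(planted_sync, 6),
        }
        nio.write_json(
            {"sync_event_times": sync.sync_event_times, "rate_per_min": sync.rate_per_min},
            outdir / "synchrony.json",
        )
        timings["calcium"] = time.perf_counter() - t0

    annotation = state_call = atlas = None
    if config.stages.chromatin:
        t0 = time.perf_counter()
        ch_cfg = dataclasses.replace(config.chromatin, seed=seeds["chromatin"])
        atlas, raw_signal, truth_ch = sd.simulate_chromatin_landscape(ch_cfg)
        nio.write_atlas_bed(atlas, outdir / "atlas.bed")
        rebuilt = ch.build_peak_atlas([atlas.intervals], merge_distance=500)
        assert len(rebuilt) == len(atlas)  # atlas is stable under merging
        raw = pd.DataFrame({f"{m}_{s}_r{r}": v for (m, s, r), v in raw_signal.items()})
        totals = raw.sum(axis=0)
        norm = ch.normalize_depth(raw, totals * 0 + 1e7)  # simulated depth is 1e7
        signal_by = {}
        for (mark, stage, rep), col in raw_signal.items():
            signal_by.setdefault((mark, stage), {})[f"r{rep}"] = col
        signal_maps = {k: pd.DataFrame(v) for k, v in signal_by.items()}
        state_call = ch.call_chromatin_states(signal_maps, stages=list(ch_cfg.stages))
        state_call.labels.rename_axis("peak").to_frame().to_csv(
            outdir / "state_calls.tsv", sep="\t"
        )
        truth_states = truth_ch.peak_states
        biv_true = truth_states == "bivalent_resolving"
        biv_recovery = float(
            (state_call.labels[biv_true] == "bivalent_resolving").mean()
        )
        overall = float((state_call.labels == truth_states).mean())
        de_marks = []
        for mark in ch_cfg.marks:
            cols_n = [f"{mark}_neuron_r{r}" for r in range(1, ch_cfg.n_replicates + 1)]
            cols_p = [f"{mark}_NPC_r{r}" for r in range(1, ch_cfg.n_replicates + 1)]
            log_n = np.log2(norm.normalized[cols_n].to_numpy() + 1)
            log_p = np.log2(norm.normalized[cols_p].to_numpy() + 1)
            from scipy import stats as sstats

            with np.errstate(invalid="ignore", divide="ignore"):
                _, pv = sstats.ttest_ind(log_n, log_p, axis=1, equal_var=False)
            lfc = log_n.mean(axis=1) - log_p.mean(axis=1)
            pv = np.where(np.isnan(pv), 1.0, pv)
            from statsmodels.stats.multitest import multipletests

            _, fdr, _, _ = multipletests(pv, method="fdr_bh")
            de_marks.append(
                tr.DETable(
                    comparison=f"{mark}_neuron_vs_NPC",
                    table=pd.DataFrame(
                        {"logFC": lfc, "pvalue": pv, "fdr": fdr}, index=norm.normalized.index
                    ),
                )
            )
        clusters = ch.cluster_differential_peaks(norm, de_marks, method="ward", n_clusters=3)
        clusters.rename_axis("peak").to_frame().to_csv(outdir / "peak_clusters.tsv", sep="\t")

        gene_models = sd.simulate_gene_models(
            atlas,
            list(tc.counts.index),
            truth_states,
            truth_expr.gene_trend_labels,
            seed=seeds["genes"],
        )
        nio.write_gene_models_tsv(gene_models, outdir / "gene_models.tsv")
        annotation = ch.annotate_peaks_to_genes(atlas, gene_models)
        tp_mean = rpkm.T.groupby(tc.samples["timepoint"].reindex(rpkm.columns)).mean().T
        tp_mean = tp_mean[[c for c in ("d25", "d50", "d75", "d100") if c in tp_mean.columns]]
        de_genes = (
            labels.index[labels != "none"].tolist()
            if labels is not None
            else truth_expr.gene_trend_labels.index[
                truth_expr.gene_trend_labels != "none"
            ].tolist()
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            profiles = ch.intersect_expression_zscores(clusters, annotation, de_genes, tp_mean)
        profiles.to_csv(outdir / "cluster_expression_profiles.tsv", sep="\t")

        # bivalent-called peaks vs planted mono_up genes (hypergeometric)
        from scipy.stats import hypergeom

        annotated = annotation.dropna()
        universe = sorted(set(annotated))
        biv_called_peaks = state_call.labels.index[state_call.labels == "bivalent_resolving"]
        biv_genes = sorted(set(annotated.reindex(biv_called_peaks).dropna()))
        up_genes = set(
            truth_expr.gene_trend_labels.index[truth_expr.gene_trend_labels == "mono_up"]
        )
        N = len(universe)
        K = len([g for g in universe if g in up_genes])
        n_g = len(biv_genes)
        k_g = len([g for g in biv_genes if g in up_genes])
        assoc_p = float(hypergeom.sf(k_g - 1, N, K, n_g)) if n_g else 1.0
        summary["chromatin"] = {
            "n_peaks": len(atlas),
            "bivalent_recovery": round(biv_recovery, 6),
            "state_accuracy": round(overall, 6),
            "n_differential_peaks": int(len(clusters)),
            "bivalent_monoup_hypergeom_p": assoc_p,
            "cluster_sizes": {int(c): int((clusters == c).sum()) for c in sorted(clusters.unique())},
        }
        timings["chromatin"] = time.perf_counter() - t0

    if config.stages.enrich:
        t0 = time.perf_counter()
        if atlas is None:
            ch_cfg = dataclasses.replace(config.chromatin, seed=seeds["chromatin"])
            atlas, _, truth_ch = sd.simulate_chromatin_landscape(ch_cfg)
            state_labels = truth_ch.peak_states
        else:
            state_labels = state_call.labels
        rng = np.random.default_rng(seeds["motifs"])
        motif_ids = [f"motif_{i:03d}" for i in range(config.n_motifs)]
        planted_set = set(
            rng.choice(motif_ids, size=config.n_planted_motifs, replace=False).tolist()
        )
        group_peaks = state_labels.index[state_labels == "bivalent_resolving"].tolist()
        groups = {"bivalent_resolving": group_peaks}
        annot_table, truth_motif = sd.simulate_motif_annotation(
            atlas,
            n_motifs=config.n_motifs,
            planted={"bivalent_resolving": planted_set},
            groups=groups,
            enrichment_factor=config.motif_enrichment_factor,
            background_rate=config.motif_background_rate,
            seed=seeds["motifs"],
        )
        nio.write_motif_annotation_tsv(annot_table, outdir / "motif_annotation.tsv")
        motif_factors = {
            m: [f"gene_{i:05d}"] for i, m in enumerate(motif_ids)
        }
        annot = en.MotifAnnotation.from_table(annot_table, motif_factors)
        res = en.motif_enrichment(group_peaks, atlas.ids, annot, group_name="bivalent_resolving")
        if rpkm is not None:
            tp_of = tc.samples["timepoint"].reindex(rpkm.columns)
            tf_rpkm = rpkm.T.groupby(tp_of).mean().T
        else:
            tf_rpkm = pd.DataFrame(
                10.0,
                index=[f"gene_{i:05d}" for i in range(config.n_motifs)],
                columns=list(en.NEURON_TIMEPOINTS),
            )
        filtered = en.filter_enriched_motifs(
            res,
            tf_rpkm,
            motif_factors,
            or_min=config.odds_ratio_min,
            rpkm_min=config.tf_rpkm_min,
            return_all=True,
        )
        filtered.reset_index().to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        hits = filtered.index[
            filtered["pass_filter"] & (filtered["fdr"] <= config.fdr_threshold)
        ]
        recall = (
            len(planted_set & set(hits)) / len(planted_set) if planted_set else float("nan")
        )
        summary["enrich"] = {
            "n_motifs": config.n_motifs,
            "n_hits": int(len(hits)),
            "planted_recall": round(float(recall), 6),
        }
        timings["enrich"] = time.perf_counter() - t0

    # timings are logged and written separately so summary.json stays
    # byte-identical for a fixed seed
    for stage, secs in timings.items():
        logger.info("stage %s: %.3f s", stage, secs)
    nio.write_json({k: round(v, 3) for k, v in timings.items()}, outdir / "timings.json")
    nio.write_json(summary, outdir / "summary.json")
    return summary
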