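"""Simulators for the multi-omic maturation time course, with ground truth.

Every downstream stage of the package is exercised on data produced here:
a six-timepoint bulk expression time course with planted monotonic trend
genes, GCaMP-style fluorescence traces with planted per-cell and
network-synchronous spike trains, a two-stage chromatin landscape with
planted state transitions for four histone marks, and motif-peak
annotations with planted group-specific enrichment.  Each simulator
returns its dataset together with a :class:`TruthBundle` carrying the
planted labels, so recovery can be measured without external data.

All simulators consume a single explicitly seeded pseudorandom stream and
are bit-reproducible for a fixed seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calcium import TraceSet
from .chromatin import GenomicInterval, PeakAtlas
from .trend import ExpressionTimecourse

DEFAULT_TIMEPOINTS = ("hPSC", "NPC", "d25", "d50", "d75", "d100")
NEURON_TIMEPOINTS = ("d25", "d50", "d75", "d100")
DEFAULT_TREATMENTS = ("DMSO", "EZH2i")
DEFAULT_MARKS = ("H3K4me3", "H3K27me3", "H3K27ac", "H3K9me3")
DEFAULT_STAGES = ("NPC", "neuron")
CHROMATIN_STATES = ("bivalent_resolving", "active_gaining", "immature_open", "stable")


@dataclass
class TruthBundle:
    """Planted ground-truth labels emitted by the simulators."""

    gene_trend_labels: pd.Series | None = None
    spike_times: dict[str, np.ndarray] | None = None
    sync_event_times: np.ndarray | None = None
    peak_states: pd.Series | None = None
    enriched_motifs: dict[str, set[str]] | None = None
    metadata: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Expression time course
# --------------------------------------------------------------------------


@dataclass
class SimExprConfig:
    """Configuration of the expression time-course simulator.

    The defaults emulate the study design: six timepoints, a DMSO and an
    inhibitor arm, three independent replicates per condition, and
    negative-binomial counts with a shared overdispersion.  Planted
    ``mono_up`` genes step up their mean log2 expression by
    ``effect_log2fc`` at every neuronal transition (d25->d50->d75->d100);
    ``mono_down`` genes mirror this.
    """

    n_genes: int = 2000
    timepoints: Sequence[str] = DEFAULT_TIMEPOINTS
    treatments: Sequence[str] = DEFAULT_TREATMENTS
    n_replicates: int = 3
    frac_mono_up: float = 0.1
    frac_mono_down: float = 0.1
    base_mean_log2: float = 6.0
    effect_log2fc: float = 1.0
    dispersion: float = 0.05
    gene_length_range: tuple[int, int] = (500, 10000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("frac_mono_up", "frac_mono_down"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_mono_up + self.frac_mono_down > 1:
            raise ValueError("frac_mono_up + frac_mono_down must be <= 1")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if self.effect_log2fc < 0:
            raise ValueError(f"effect_log2fc must be >= 0, got {self.effect_log2fc}")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid gene_length_range {self.gene_length_range}")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2.

    For very small dispersion the NB shape parameter overflows usefully
    into the Poisson limit, which is drawn directly.
    """
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_expression_timecourse(
    config: SimExprConfig,
) -> tuple[ExpressionTimecourse, TruthBundle]:
    """Simulate the count matrix, metadata and gene lengths of a time course.

    Planted mono_up genes have strictly increasing mean log2 expression
    across the neuronal transitions (by ``effect_log2fc`` per step);
    mono_down genes decrease; all other genes share a flat mean at
    ``base_mean_log2``.  Counts are negative-binomial around these means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"gene_{i:05d}" for i in range(n)]

    n_up = int(round(config.frac_mono_up * n))
    n_down = int(round(config.frac_mono_down * n))
    labels = pd.Series("none", index=genes, dtype=object, name="trend")
    labels.iloc[:n_up] = "mono_up"
    labels.iloc[n_up : n_up + n_down] = "mono_down"

    step = {tp: i for i, tp in enumerate(NEURON_TIMEPOINTS)}
    n_steps = len(NEURON_TIMEPOINTS) - 1
    is_up = (labels == "mono_up").to_numpy()
    is_down = (labels == "mono_down").to_numpy()

    columns, data = [], []
    meta = []
    for treatment in config.treatments:
        for tp in config.timepoints:
            k = step.get(tp, 0)  # progenitor stages sit at the d25 baseline
            # up genes climb from baseline; down genes start high (they
            # are expressed early) and decay to baseline, which keeps the
            # library composition balanced across timepoints
            log2_mean = np.full(n, config.base_mean_log2)
            log2_mean[is_up] += config.effect_log2fc * k
            log2_mean[is_down] += config.effect_log2fc * (n_steps - k)
            mu = np.exp2(log2_mean)
            for rep in range(1, config.n_replicates + 1):
                name = f"{treatment}_{tp}_r{rep}"
                columns.append(name)
                meta.append((name, tp, treatment, rep))
                data.append(_nb_counts(rng, mu, config.dispersion))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    samples = pd.DataFrame(
        meta, columns=["sample", "timepoint", "treatment", "replicate"]
    ).set_index("sample")
    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n),
        index=genes,
        name="length_bp",
    )
    tc = ExpressionTimecourse(counts=counts, gene_lengths=lengths, samples=samples)
    truth = TruthBundle(gene_trend_labels=labels, metadata={"seed": config.seed})
    return tc, truth


# --------------------------------------------------------------------------
# Calcium traces
# --------------------------------------------------------------------------


@dataclass
class SimCalciumConfig:
    """Configuration of the fluorescence-trace simulator.

    Emulates ~3 min GCaMP recordings at ~5 frames per second.  Each ROI
    fires private Poisson events at ``cell_rate_per_min`` plus network
    events at ``sync_rate_per_min`` in which it participates with
    probability ``sync_participation``.  Events add an instantaneous jump
    of truncated-normal amplitude (in dF/F0 units) decaying exponentially
    with ``decay_tau_s`` on top of ``baseline_f0``, plus Gaussian noise.

    Event times are quantized to the frame grid, so a planted amplitude is
    exactly representable in the sampled trace.  ``min_event_gap_s`` > 0
    thins events closer than the gap (biasing realized rates slightly
    downward); the default of 0 keeps pure Poisson statistics.
    """

    n_rois: int = 30
    duration_s: float = 180.0
    frame_rate_hz: float = 5.0
    cell_rate_per_min: float = 3.0
    sync_rate_per_min: float = 2.0
    sync_participation: float = 0.9
    amp_mean: float = 1.0
    amp_sd: float = 0.1
    decay_tau_s: float = 1.5
    baseline_f0: float = 100.0
    noise_sd: float = 0.0
    min_event_gap_s: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration_s and frame_rate_hz must be > 0")
        if self.duration_s * self.frame_rate_hz < 10:
            raise ValueError("recording must span >= 10 frames")
        if self.amp_mean <= 0:
            raise ValueError(f"amp_mean must be > 0, got {self.amp_mean}")
        if self.baseline_f0 <= 0:
            raise ValueError(f"baseline_f0 must be > 0, got {self.baseline_f0}")
        if not 0 < self.sync_participation <= 1:
            raise ValueError("sync_participation must be in (0, 1]")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")


def _poisson_times(
    rng: np.random.Generator, rate_per_min: float, duration_s: float
) -> np.ndarray:
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _thin(times: np.ndarray, min_gap: float) -> np.ndarray:
    if min_gap <= 0 or len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_gap:
            kept.append(t)
    return np.asarray(kept)


def simulate_calcium_traces(config: SimCalciumConfig) -> tuple[TraceSet, TruthBundle]:
    """Simulate ROI fluorescence traces with planted spikes and synchrony."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_s * config.frame_rate_hz))
    dt = 1.0 / config.frame_rate_hz
    time_s = np.arange(n_frames) * dt

    def snap(times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.round(times / dt).astype(int), 0, n_frames - 1)
        return np.unique(idx) * dt

    sync_times = snap(_thin(_poisson_times(rng, config.sync_rate_per_min, config.duration_s),
                            config.min_event_gap_s))
    rois = [f"roi_{i:03d}" for i in range(config.n_rois)]
    spike_times: dict[str, np.ndarray] = {}
    F = np.empty((config.n_rois, n_frames))
    for i, roi in enumerate(rois):
        private = snap(_thin(_poisson_times(rng, config.cell_rate_per_min, config.duration_s),
                             config.min_event_gap_s))
        member = rng.random(len(sync_times)) < config.sync_participation
        events = np.unique(np.concatenate([private, sync_times[member]]))
        events = _thin(events, config.min_event_gap_s)
        spike_times[roi] = events
        # truncated-normal amplitudes (resample below zero)
        amps = rng.normal(config.amp_mean, config.amp_sd, size=len(events))
        while (amps <= 0).any():
            bad = amps <= 0
            amps[bad] = rng.normal(config.amp_mean, config.amp_sd, size=bad.sum())
        dff = np.zeros(n_frames)
        for t0, a in zip(events, amps):
            after = time_s >= t0 - 1e-9
            dff[after] += a * np.exp(-(time_s[after] - t0) / config.decay_tau_s)
        F[i] = config.baseline_f0 * (1.0 + dff)
        if config.noise_sd > 0:
            F[i] += rng.normal(0.0, config.noise_sd, size=n_frames)
    traces = TraceSet(time_s=time_s, F=pd.DataFrame(F, index=rois, columns=np.arange(n_frames)),
                      frame_rate_hz=config.frame_rate_hz)
    truth = TruthBundle(
        spike_times=spike_times,
        sync_event_times=sync_times,
        metadata={"seed": config.seed, "duration_s": config.duration_s},
    )
    return traces, truth


# --------------------------------------------------------------------------
# Chromatin landscape
# --------------------------------------------------------------------------


@dataclass
class SimChromatinConfig:
    """Configuration of the two-stage chromatin-landscape simulator.

    Four histone marks are profiled at the NPC and neuron stages.  Peaks
    are placed without overlap and with pairwise gaps > 500 bp so the
    atlas is stable under merging.  Mark signal per peak follows the
    planted state template:

    - ``bivalent_resolving``: H3K4me3 + H3K27me3 high in NPC; H3K4me3 +
      H3K27ac high and H3K27me3 low in neurons (poised chromatin resolved
      to active).
    - ``active_gaining``: low in NPC; H3K4me3 + H3K27ac high in neurons.
    - ``immature_open``: H3K4me3 + H3K27ac high in NPC only.
    - ``stable``: background signal at both stages.

    Counts are Poisson around ``signal_high``/``signal_low``, scaled to
    per-sample library sizes.
    """

    n_peaks: int = 2000
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 8_000_000, "chr2": 8_000_000}
    )
    state_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "bivalent_resolving": 0.25,
            "active_gaining": 0.25,
            "immature_open": 0.2,
            "stable": 0.3,
        }
    )
    marks: Sequence[str] = DEFAULT_MARKS
    stages: Sequence[str] = DEFAULT_STAGES
    n_replicates: int = 2
    signal_high: float = 100.0
    signal_low: float = 5.0
    peak_width: int = 400
    min_gap: int = 501
    library_sizes: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.state_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state_fractions must sum to 1, got {total}")
        unknown = set(self.state_fractions) - set(CHROMATIN_STATES)
        if unknown:
            raise ValueError(f"unknown chromatin states: {sorted(unknown)}")
        if not self.signal_high > self.signal_low >= 0:
            raise ValueError("need signal_high > signal_low >= 0")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")


#: mark-presence template per state and stage (True = high signal)
_STATE_TEMPLATES: dict[str, dict[str, dict[str, bool]]] = {
    "bivalent_resolving": {
        "NPC": {"H3K4me3": True, "H3K27me3": True, "H3K27ac": False, "H3K9me3": False},
        "neuron": {"H3K4me3": True, "H3K27me3": False, "H3K27ac": True, "H3K9me3": False},
    },
    "active_gaining": {
        "NPC": {"H3K4me3": False, "H3K27me3": False, "H3K27ac": False, "H3K9me3": False},
        "neuron": {"H3K4me3": True, "H3K27me3": False, "H3K27ac": True, "H3K9me3": False},
    },
    "immature_open": {
        "NPC": {"H3K4me3": True, "H3K27me3": False, "H3K27ac": True, "H3K9me3": False},
        "neuron": {"H3K4me3": False, "H3K27me3": False, "H3K27ac": False, "H3K9me3": False},
    },
    "stable": {
        "NPC": {"H3K4me3": False, "H3K27me3": False, "H3K27ac": False, "H3K9me3": False},
        "neuron": {"H3K4me3": False, "H3K27me3": False, "H3K27ac": False, "H3K9me3": False},
    },
}


def _place_peaks(config: SimChromatinConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    """Evenly spread non-overlapping peaks with pairwise gaps > 500 bp."""
    chroms = sorted(config.chrom_sizes)
    jitter_max = max(1, config.min_gap // 4)
    # pitch leaves jitter_max of slack per slot so any jitter combination
    # keeps pairwise gaps >= min_gap
    pitch = config.peak_width + config.min_gap + jitter_max
    capacity = {c: max(0, (config.chrom_sizes[c] - 1000) // pitch) for c in chroms}
    if sum(capacity.values()) < config.n_peaks:
        raise ValueError(
            f"chrom_sizes too small to place {config.n_peaks} peaks "
            f"with width {config.peak_width} and gap {config.min_gap}"
        )
    intervals: list[GenomicInterval] = []
    remaining = config.n_peaks
    for c in chroms:
        take = min(remaining, capacity[c])
        jitter = rng.integers(0, jitter_max + 1, size=take)
        for i in range(take):
            start = 500 + i * pitch + int(jitter[i])
            intervals.append(GenomicInterval(c, start, start + config.peak_width))
        remaining -= take
        if remaining == 0:
            break
    return intervals


def simulate_chromatin_landscape(
    config: SimChromatinConfig,
) -> tuple[PeakAtlas, dict[tuple[str, str, int], pd.Series], TruthBundle]:
    """Simulate a peak atlas plus per-(mark, stage, replicate) raw counts.

    Returns the atlas, a mapping (mark, stage, replicate) -> per-peak raw
    fragment counts (Series indexed by peak id), and the planted truth.
    Library sizes default to 1e7 fragments per sample so the depth
    normalization is the identity unless configured otherwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    intervals = _place_peaks(config, rng)
    atlas = PeakAtlas.from_intervals(intervals, provenance=["simulated"])
    peak_ids = atlas.ids

    # deterministic state assignment: exact fractions, shuffled
    counts_per_state = {}
    assigned = 0
    states = [s for s in CHROMATIN_STATES if s in config.state_fractions]
    for s in states[:-1]:
        counts_per_state[s] = int(round(config.state_fractions[s] * config.n_peaks))
        assigned += counts_per_state[s]
    counts_per_state[states[-1]] = config.n_peaks - assigned
    state_arr = np.concatenate([[s] * counts_per_state[s] for s in states])
    rng.shuffle(state_arr)
    peak_states = pd.Series(state_arr, index=peak_ids, name="state")

    signal: dict[tuple[str, str, int], pd.Series] = {}
    target = 1e7
    for mark in config.marks:
        for stage in config.stages:
            high = np.array(
                [_STATE_TEMPLATES[s][stage].get(mark, False) for s in state_arr]
            )
            mu = np.where(high, config.signal_high, config.signal_low)
            for rep in range(1, config.n_replicates + 1):
                key = (mark, stage, rep)
                lib = (config.library_sizes or {}).get(f"{mark}_{stage}_r{rep}", target)
                scale = lib / target
                signal[key] = pd.Series(
                    rng.poisson(mu * scale), index=peak_ids, name=f"{mark}_{stage}_r{rep}"
                )
    truth = TruthBundle(peak_states=peak_states, metadata={"seed": config.seed})
    return atlas, signal, truth


def simulate_gene_models(
    atlas: PeakAtlas,
    gene_ids: Sequence[str],
    peak_states: pd.Series,
    trend_labels: pd.Series,
    bivalent_to_up_rate: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay one gene body over each atlas peak, linking chromatin to expression.

    Each peak gets an overlapping gene model so peak->gene annotation is
    unambiguous.  Planted ``bivalent_resolving`` peaks draw their gene id
    from the planted ``mono_up`` genes with probability
    ``bivalent_to_up_rate`` (without replacement while available); all
    other peaks draw from the remaining pool.  Returns a gene-model table
    with columns gene_id, chrom, start, end, strand.
    """
    rng = np.random.default_rng(seed)
    up_pool = [g for g in trend_labels.index if trend_labels[g] == "mono_up" and g in gene_ids]
    other_pool = [g for g in gene_ids if g not in set(up_pool)]
    rng.shuffle(up_pool)
    rng.shuffle(other_pool)
    rows = []
    df = atlas.to_frame()
    for _, peak in df.iterrows():
        is_biv = peak_states.get(peak["name"]) == "bivalent_resolving"
        take_up = is_biv and up_pool and rng.random() < bivalent_to_up_rate
        if take_up:
            gene = up_pool.pop()
        elif other_pool:
            gene = other_pool.pop()
        elif up_pool:
            gene = up_pool.pop()
        else:
            break  # more peaks than genes: leave the rest unannotated
        strand = "+" if rng.random() < 0.5 else "-"
        start = max(0, int(peak["start"]) - 100)
        end = int(peak["end"]) + 100
        rows.append((gene, peak["chrom"], start, end, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# --------------------------------------------------------------------------
# Motif annotation
# --------------------------------------------------------------------------


def simulate_motif_annotation(
    atlas: PeakAtlas,
    n_motifs: int,
    planted: Mapping[str, set[str]],
    groups: Mapping[str, Sequence[str]],
    enrichment_factor: float = 2.5,
    background_rate: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Bernoulli motif-peak annotation with planted group enrichment.

    Background presence is Bernoulli(``background_rate``) per peak and
    motif; a planted motif is present in the peaks of its group at rate
    ``min(1, enrichment_factor * background_rate)``.  ``groups`` maps a
    group label to member peak ids (a partition of a subset of the atlas).
    Returns a (peak_id, motif_id) annotation table and the truth.
    """
    if enrichment_factor <= 1:
        raise ValueError(f"enrichment_factor must be > 1, got {enrichment_factor}")
    rng = np.random.default_rng(seed)
    peak_ids = list(atlas.ids)
    id_set = set(peak_ids)
    for group, members in groups.items():
        stray = set(members) - id_set
        if stray:
            raise ValueError(f"group {group!r} has peaks outside the atlas: {sorted(stray)[:5]}")
    motifs = [f"motif_{i:03d}" for i in range(n_motifs)]
    unknown = {m for ms in planted.values() for m in ms} - set(motifs)
    if unknown:
        raise ValueError(f"planted motifs outside the motif universe: {sorted(unknown)}")

    group_of: dict[str, str] = {}
    for group, members in groups.items():
        for p in members:
            group_of[p] = group
    in_rate = min(1.0, enrichment_factor * background_rate)
    rows = []
    for motif in motifs:
        enriched_groups = {g for g, ms in planted.items() if motif in ms}
        for p in peak_ids:
            rate = in_rate if group_of.get(p) in enriched_groups else background_rate
            if rng.random() < rate:
                rows.append((p, motif))
    annot = pd.DataFrame(rows, columns=["peak_id", "motif_id"])
    truth = TruthBundle(
        enriched_motifs={g: set(ms) for g, ms in planted.items()},
        metadata={"seed": seed, "background_rate": background_rate},
    )
    return annot, truth
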