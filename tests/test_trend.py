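"""Unit tests for RPKM, presence filtering, the stand-in DE test and the
monotonic trend rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuromat import trend as tr

from conftest import make_de_tables, random_de_tables


# ---------------------------------------------------------------------------
# literal brute-force evaluation of the printed monotonic rules (oracle)
# ---------------------------------------------------------------------------


def oracle_monotonic(lfc, fdr, direction, mode, thr=0.05):
    """Transliteration of the trend rules, one gene at a time.

    ``lfc``/``fdr`` map comparison name -> value.
    """
    s = {c: fdr[c] <= thr for c in tr.COMPARISONS}
    f = lfc
    if direction == "up" and mode == "strict":
        return (
            s["d50_vs_d25"] and s["d100_vs_d25"] and s["d100_vs_d50"]
            and f["d50_vs_d25"] > 0 and f["d75_vs_d50"] > 0
            and f["d100_vs_d25"] > f["d50_vs_d25"]
        )
    if direction == "down" and mode == "strict":
        return (
            s["d50_vs_d25"] and s["d100_vs_d25"] and s["d100_vs_d50"]
            and f["d50_vs_d25"] < 0 and f["d75_vs_d50"] < 0
            and f["d100_vs_d25"] < f["d50_vs_d25"]
        )
    if direction == "up" and mode == "relaxed":
        return (
            s["d100_vs_d25"] and f["d50_vs_d25"] > 0
            and (f["d100_vs_d25"] >= f["d50_vs_d25"] or f["d75_vs_d50"] > 0)
        )
    if direction == "down" and mode == "relaxed":
        return (
            s["d100_vs_d25"] and f["d50_vs_d25"] < 0
            and (f["d100_vs_d25"] <= f["d50_vs_d25"] or f["d75_vs_d50"] < 0)
        )
    raise ValueError


# ---------------------------------------------------------------------------
# RPKM and presence
# ---------------------------------------------------------------------------


class TestRpkm:
    def test_direct_formula(self):
        # 100 counts on a 2 kb gene in a 10M library -> 5 RPKM
        counts = pd.DataFrame({"s1": [100, 9_999_900]}, index=["g1", "g2"])
        tc = tr.ExpressionTimecourse(
            counts=counts,
            gene_lengths=pd.Series([2000, 1000], index=["g1", "g2"]),
            samples=pd.DataFrame(
                {"timepoint": ["d25"], "treatment": ["DMSO"], "replicate": [1]}, index=["s1"]
            ),
        )
        rpkm = tr.compute_rpkm(tc)
        assert rpkm.loc["g1", "s1"] == pytest.approx(5.0)

    def test_zero_count_maps_to_zero(self, small_timecourse):
        tc = small_timecourse
        tc.counts.loc["flat1", tc.counts.columns[0]] = 0
        rpkm = tr.compute_rpkm(tc)
        assert rpkm.loc["flat1", tc.counts.columns[0]] == 0.0

    def test_uniform_column_scaling_invariance(self, small_timecourse):
        rpkm = tr.compute_rpkm(small_timecourse)
        scaled = small_timecourse
        col = scaled.counts.columns[0]
        scaled.counts[col] = scaled.counts[col] * 3
        rpkm2 = tr.compute_rpkm(scaled)
        pd.testing.assert_series_equal(rpkm[col], rpkm2[col])

    def test_zero_library_errors(self, small_timecourse):
        small_timecourse.counts.iloc[:, 0] = 0
        with pytest.raises(ValueError, match="library"):
            tr.compute_rpkm(small_timecourse)


class TestPresenceFilter:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0.2, 0.9, 1.0, 0.0), True),  # reaches 1 RPKM in one sample
            ((0.0, 0.0, 0.0, 0.0), False),
            ((0.99, 0.99, 0.99, 0.99), False),
        ],
    )
    def test_threshold_rule(self, row, expected):
        rpkm = pd.DataFrame([row], index=["g"], columns=list("abcd"))
        assert ("g" in tr.presence_filter(rpkm)) is expected

    def test_zero_threshold_vacuous(self):
        rpkm = pd.DataFrame(np.zeros((3, 2)), index=list("xyz"))
        assert list(tr.presence_filter(rpkm, threshold=0)) == list("xyz")

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            tr.presence_filter(pd.DataFrame([[1.0]]), threshold=-1)


# ---------------------------------------------------------------------------
# naive differential
# ---------------------------------------------------------------------------


class TestNaiveDifferential:
    def test_identical_groups_null(self, small_timecourse):
        tc = small_timecourse
        # duplicate the d25 data into fake "d50" columns
        a = tc.select_samples(timepoint="d25")
        rpkm = tr.compute_rpkm(tc)
        dup = rpkm.copy()
        dup[["fakeB1", "fakeB2"]] = rpkm[a].to_numpy()
        de = tr.naive_differential(tc, a, ["fakeB1", "fakeB2"], rpkm=dup)
        assert np.allclose(de.table["logFC"], 0)
        assert np.allclose(de.table["pvalue"], 1.0)

    def test_bh_hand_computation(self):
        from statsmodels.stats.multitest import multipletests

        _, fdr, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(fdr, [0.04, 0.04, 0.04, 0.04])

    def test_planted_fold_change_sign(self):
        from neuromat import synthdata as sd

        tc, truth = sd.simulate_expression_timecourse(
            sd.SimExprConfig(n_genes=500, effect_log2fc=2.0, dispersion=0.05, seed=13)
        )
        de = tr.naive_differential(
            tc,
            tc.select_samples(timepoint="d100", treatment="DMSO"),
            tc.select_samples(timepoint="d25", treatment="DMSO"),
        )
        up = truth.gene_trend_labels == "mono_up"
        down = truth.gene_trend_labels == "mono_down"
        sign_ok = (de.table.loc[up.index[up], "logFC"] > 0).mean()
        sign_ok_dn = (de.table.loc[down.index[down], "logFC"] < 0).mean()
        assert sign_ok >= 0.99 and sign_ok_dn >= 0.99

    def test_group_validation(self, small_timecourse):
        a = small_timecourse.select_samples(timepoint="d25")
        with pytest.raises(ValueError, match="overlap"):
            tr.naive_differential(small_timecourse, a, a)
        with pytest.raises(ValueError, match=">= 2"):
            tr.naive_differential(small_timecourse, a[:1], a[1:])


# ---------------------------------------------------------------------------
# monotonic classification
# ---------------------------------------------------------------------------


class TestClassifyMonotonic:
    def _single_gene(self, d50v25, d75v50, d100v50, d100v25):
        return make_de_tables(
            ["g"],
            {
                "d50_vs_d25": [d50v25],
                "d75_vs_d50": [d75v50],
                "d100_vs_d50": [d100v50],
                "d100_vs_d25": [d100v25],
            },
        )

    def test_strict_up_example(self):
        de = self._single_gene((1.2, 0.01), (0.3, 0.2), (0.5, 0.01), (2.0, 0.001))
        assert tr.classify_monotonic(de, "up", "strict")["g"]
        assert tr.classify_monotonic(de, "up", "relaxed")["g"]

    def test_fails_both_modes(self):
        # negative intermediate step and shrinking overall fold change
        de = self._single_gene((1.2, 0.01), (-0.1, 0.2), (0.5, 0.01), (1.0, 0.001))
        assert not tr.classify_monotonic(de, "up", "strict")["g"]
        assert not tr.classify_monotonic(de, "up", "relaxed")["g"]

    def test_down_relaxed_example(self):
        de = self._single_gene((-0.5, 0.2), (-0.2, 0.4), (-1.0, 0.2), (-2.0, 0.001))
        assert tr.classify_monotonic(de, "down", "relaxed")["g"]
        assert not tr.classify_monotonic(de, "down", "strict")["g"]

    def test_missing_table_errors(self):
        de = self._single_gene((1, 0.01), (1, 0.01), (1, 0.01), (2, 0.01))
        del de["d75_vs_d50"]
        with pytest.raises(ValueError, match="d75_vs_d50"):
            tr.classify_monotonic(de, "up", "strict")

    def test_gene_missing_from_one_table_is_none(self):
        de = self._single_gene((1.2, 0.01), (0.3, 0.01), (0.5, 0.01), (2.0, 0.001))
        de["d100_vs_d25"].table.drop(index="g", inplace=True)
        labels = tr.trend_labels(de)
        assert labels["g"] == "none"

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        genes, de = random_de_tables(rng, 10_000)
        for direction in ("up", "down"):
            for mode in ("strict", "relaxed"):
                fast = tr.classify_monotonic(de, direction, mode)
                for g in genes:
                    lfc = {c: de[c].table.loc[g, "logFC"] for c in tr.COMPARISONS}
                    fdr = {c: de[c].table.loc[g, "fdr"] for c in tr.COMPARISONS}
                    assert fast[g] == oracle_monotonic(lfc, fdr, direction, mode), g

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_strict_subset_of_relaxed_and_direction_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        _, de = random_de_tables(rng, 40)
        for direction in ("up", "down"):
            strict = tr.classify_monotonic(de, direction, "strict")
            relaxed = tr.classify_monotonic(de, direction, "relaxed")
            assert (strict <= relaxed).all()
        up = tr.classify_monotonic(de, "up", "relaxed")
        down = tr.classify_monotonic(de, "down", "relaxed")
        assert not (up & down).any()


class TestMarkerSelection:
    def _setup(self, max_lfc, peak_rpkm, sem):
        genes = ["g"]
        de = make_de_tables(
            genes,
            {c: [(max_lfc if c == "d100_vs_d25" else 0.1, 0.01)] for c in tr.COMPARISONS},
        )
        rpkm = pd.DataFrame({"d25": [0.5], "d100": [peak_rpkm]}, index=genes)
        labels = pd.Series(["mono_up_relaxed"], index=genes)
        sems = pd.Series([sem], index=genes)
        return labels, rpkm, de, sems

    @pytest.mark.parametrize(
        "max_lfc,peak,sem,kept",
        [
            (1.5, 8.0, 0.4, True),   # passes all three criteria
            (0.9, 50.0, 0.1, False), # fold change too small, expression irrelevant
            (1.5, 8.0, 1.0, False),  # sem boundary is strict (< 1)
            (1.5, 4.0, 0.4, False),  # peak expression below 5 RPKM
        ],
    )
    def test_criteria(self, max_lfc, peak, sem, kept):
        labels, rpkm, de, sems = self._setup(max_lfc, peak, sem)
        out = tr.select_marker_genes(labels, rpkm, de, sems)
        assert ("g" in out) is kept

    def test_missing_sem_errors(self):
        labels, rpkm, de, _ = self._setup(1.5, 8.0, 0.4)
        with pytest.raises(ValueError, match="sem"):
            tr.select_marker_genes(labels, rpkm, de, pd.Series(dtype=float))
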