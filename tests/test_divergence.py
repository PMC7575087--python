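"""EDI, profile F test, seawater interaction, clustering, pair report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ohnodiverge import divergence
from ohnodiverge.divergence import (
    cluster_profiles,
    compute_edi,
    edi_table,
    interaction_test,
    pair_divergence_report,
    profile_divergence_test,
)
from ohnodiverge.simdata import archetype_profiles

TIMES = np.repeat(np.arange(5, 30, 4), 3).astype(float)


class TestEdi:
    @pytest.mark.parametrize("a, b, expected", [(8, 2, 2.0), (2, 8, 2.0), (5, 5, 0.0)])
    def test_examples(self, a, b, expected):
        assert compute_edi(a, b) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_edi(-1.0, 2.0)

    def test_zero_handling_engages_offset_symmetrically(self):
        assert compute_edi(0.0, 0.0) == 0.0
        assert compute_edi(0.0, 3.0) == pytest.approx(compute_edi(3.0, 0.0))
        assert np.isfinite(compute_edi(0.0, 3.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 1e6),
        b=st.floats(0.01, 1e6),
        c=st.floats(0.01, 1e3),
    )
    def test_symmetry_and_scale_invariance(self, a, b, c):
        assert compute_edi(a, b) == pytest.approx(compute_edi(b, a), rel=1e-9)
        assert compute_edi(c * a, c * b) == pytest.approx(compute_edi(a, b), abs=1e-9)
        assert compute_edi(a, a) == 0.0


class TestEdiTable:
    @staticmethod
    def _atlas(n_tissues=11):
        tissues = [f"t{i}" for i in range(n_tissues)]
        samples = [f"{t}_r{r}" for t in tissues for r in range(2)]
        meta = pd.DataFrame(
            {"tissue": [s.rsplit("_", 1)[0] for s in samples], "condition": "atlas"},
            index=pd.Index(samples, name="sample"),
        )
        return tissues, meta

    def test_identical_rows_give_zero_median(self):
        tissues, meta = self._atlas()
        row = np.arange(1.0, len(meta) + 1)
        expr = pd.DataFrame([row, row], index=["a", "b"], columns=meta.index)
        pairs = pd.DataFrame([{"gene1": "a", "gene2": "b", "orthogroup": "OG1"}])
        records, summary = edi_table(pairs, expr, meta)
        assert (records.edi == 0).all()
        assert summary.median_edi.iloc[0] == 0.0

    def test_median_of_planted_sequence(self):
        tissues, meta = self._atlas(11)
        base = np.ones(len(meta))
        g2 = np.concatenate([[2.0 ** k] * 2 for k in range(11)])
        expr = pd.DataFrame([base, g2], index=["a", "b"], columns=meta.index)
        pairs = pd.DataFrame([{"gene1": "a", "gene2": "b", "orthogroup": "OG1"}])
        records, summary = edi_table(pairs, expr, meta)
        assert sorted(records.edi) == pytest.approx(list(range(11)))
        assert summary.median_edi.iloc[0] == pytest.approx(5.0)

    def test_matches_bruteforce_recompute(self):
        rng = np.random.default_rng(0)
        tissues, meta = self._atlas(6)
        genes = [f"g{i}" for i in range(20)]
        expr = pd.DataFrame(rng.exponential(50, size=(20, len(meta))),
                            index=genes, columns=meta.index)
        pairs = pd.DataFrame(
            [{"gene1": genes[2 * i], "gene2": genes[2 * i + 1], "orthogroup": f"OG{i}"}
             for i in range(10)]
        )
        records, summary = edi_table(pairs, expr, meta)
        for row in records.itertuples():
            g1 = pairs.loc[pairs.orthogroup == row.pair, "gene1"].iloc[0]
            g2 = pairs.loc[pairs.orthogroup == row.pair, "gene2"].iloc[0]
            cols = meta.index[meta.tissue == row.tissue]
            expect = abs(np.log2(expr.loc[g1, cols].mean() / expr.loc[g2, cols].mean()))
            assert row.edi == pytest.approx(expect, abs=1e-12)

    def test_missing_gene_flagged_and_excluded(self):
        tissues, meta = self._atlas(3)
        expr = pd.DataFrame([np.ones(len(meta))], index=["a"], columns=meta.index)
        pairs = pd.DataFrame([{"gene1": "a", "gene2": "ghost", "orthogroup": "OG1"}])
        records, summary = edi_table(pairs, expr, meta)
        assert records.empty
        assert summary.flagged_missing.iloc[0]


def _ols_f_oracle(y1, y2, t, order=6):
    """Independent nested-model F via statsmodels OLS on dummies."""

    import statsmodels.api as sm

    y = np.concatenate([y1 / y1.mean(), y2 / y2.mean()])
    tc = np.concatenate([t, t]) - t.mean()
    g = np.concatenate([np.zeros(len(t)), np.ones(len(t))])
    Xs = np.vander(tc, N=order + 1, increasing=True)
    X_shared = Xs
    X_sep = np.column_stack([Xs * (1 - g)[:, None], Xs * g[:, None]])
    fit_sh = sm.OLS(y, X_shared).fit()
    fit_sep = sm.OLS(y, X_sep).fit()
    f, p, _ = fit_sep.compare_f_test(fit_sh)
    return float(f), float(p)


class TestProfileDivergence:
    def test_identical_series(self):
        rng = np.random.default_rng(1)
        y = 10 + 3 * np.cos(2 * np.pi * TIMES / 24) + rng.normal(0, 0.2, len(TIMES))
        res = profile_divergence_test(y, y, TIMES)
        assert res.F == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)
        assert res.rss_separate <= res.rss_shared + 1e-12

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y1 = np.abs(10 + rng.normal(0, 2, len(TIMES)))
            y2 = np.abs(10 + rng.normal(0, 2, len(TIMES)))
            res = profile_divergence_test(y1, y2, TIMES)
            f, p = _ols_f_oracle(y1, y2, TIMES)
            assert res.F == pytest.approx(f, abs=1e-8, rel=1e-8)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_symmetric_in_series_order(self):
        rng = np.random.default_rng(3)
        y1 = np.abs(10 + rng.normal(0, 2, len(TIMES)))
        y2 = np.abs(12 + rng.normal(0, 2, len(TIMES)))
        a = profile_divergence_test(y1, y2, TIMES)
        b = profile_divergence_test(y2, y1, TIMES)
        assert a.F == pytest.approx(b.F, rel=1e-12)

    def test_null_rejection_rate(self):
        """Same underlying curve + noise: P(p<0.01) within [0.005, 0.02]."""

        rng = np.random.default_rng(4)
        rejections = 0
        n_pairs = 1000
        base = 10 + 2 * np.cos(2 * np.pi * (TIMES - 9) / 24)
        for _ in range(n_pairs):
            y1 = base + rng.normal(0, 0.5, len(TIMES))
            y2 = base + rng.normal(0, 0.5, len(TIMES))
            if profile_divergence_test(y1, y2, TIMES).p < 0.01:
                rejections += 1
        assert 0.005 <= rejections / n_pairs <= 0.02

    def test_too_few_distinct_times_rejected(self):
        t = np.repeat([0.0, 4.0, 8.0], 5)
        y = np.abs(np.random.default_rng(5).normal(10, 1, len(t)))
        with pytest.raises(ValueError, match="distinct"):
            profile_divergence_test(y, y, t)


def _anova_oracle(cells):
    """statsmodels two-way ANOVA interaction F/p on the same log2 data."""

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frames = []
    for (copy, cond), vals in cells.items():
        frames.append(pd.DataFrame({"y": np.log2(np.asarray(vals) + 0.5),
                                    "copy": copy, "cond": cond}))
    df = pd.concat(frames)
    fit = smf.ols("y ~ C(copy) * C(cond)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(copy):C(cond)"]
    return float(row.F), float(row["PR(>F)"])


class TestInteraction:
    def test_identical_responses_no_interaction(self):
        res = interaction_test([10, 11, 9, 10, 11, 10], [40, 42, 38, 41, 39, 40],
                               [10, 10, 11, 9, 10, 11], [40, 41, 39, 40, 42, 38])
        assert res.interaction_p > 0.5
        assert not res.divergent

    def test_power_on_planted_divergence(self):
        """log2FC 2 vs 0, sd 0.25, n=6: detected at p<0.05 in >=95% of seeds."""

        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            g1fw = 10 * 2 ** rng.normal(0, 0.25, 6)
            g1sw = 40 * 2 ** rng.normal(0, 0.25, 6)
            g2fw = 10 * 2 ** rng.normal(0, 0.25, 6)
            g2sw = 10 * 2 ** rng.normal(0, 0.25, 6)
            if interaction_test(g1fw, g1sw, g2fw, g2sw).interaction_p < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_matches_statsmodels_anova(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            cells = {
                ("g1", "FW"): rng.exponential(20, 6),
                ("g1", "SW"): rng.exponential(35, 6),
                ("g2", "FW"): rng.exponential(20, 6),
                ("g2", "SW"): rng.exponential(20, 6),
            }
            res = interaction_test(cells[("g1", "FW")], cells[("g1", "SW")],
                                   cells[("g2", "FW")], cells[("g2", "SW")])
            f, p = _anova_oracle(cells)
            assert res.F == pytest.approx(f, rel=1e-8)
            assert res.interaction_p == pytest.approx(p, rel=1e-8)

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            interaction_test([1], [2, 3], [4, 5], [6, 7])


class TestClustering:
    def test_archetype_recovery(self):
        rng = np.random.default_rng(7)
        prof = archetype_profiles(6, 5)
        rows, labels = [], []
        for a in range(5):
            for g in range(40):
                rows.append(prof[a] + rng.normal(0, 0.2, 6))
                labels.append(a)
        df = pd.DataFrame(rows, index=[f"g{i:03d}" for i in range(200)])
        assign, means = cluster_profiles(df, k=5)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels, assign.to_numpy()) >= 0.9
        assign2, _ = cluster_profiles(df, k=5)
        pd.testing.assert_series_equal(assign, assign2)

    def test_identical_profiles_share_cluster(self):
        rng = np.random.default_rng(8)
        prof = archetype_profiles(6, 5)
        rows = {f"g{i}": prof[i % 5] + rng.normal(0, 0.1, 6) for i in range(20)}
        rows["twin_a"] = prof[0]
        rows["twin_b"] = prof[0].copy()
        df = pd.DataFrame.from_dict(rows, orient="index")
        assign, _ = cluster_profiles(df, k=5)
        assert assign["twin_a"] == assign["twin_b"]

    def test_anticorrelated_profiles_split(self):
        """Distance of perfectly anti-correlated profiles is the maximum 2."""

        x = np.array([1.0, 2, 3, 4, 5, 6])
        from scipy.spatial.distance import correlation

        assert correlation(x, -x) == pytest.approx(2.0)
        rng = np.random.default_rng(9)
        rows = {"up": x, "down": -x}
        for i in range(10):
            rows[f"f{i}"] = x + rng.normal(0, 0.1, 6)
        assign, _ = cluster_profiles(pd.DataFrame.from_dict(rows, orient="index"), k=2)
        assert assign["up"] != assign["down"]

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        prof = archetype_profiles(6, 5)
        rows = [prof[i % 5] + rng.normal(0, 0.15, 6) for i in range(50)]
        df = pd.DataFrame(rows, index=[f"g{i:02d}" for i in range(50)])
        scaled = df.mul(rng.uniform(0.5, 5, 50), axis=0).add(rng.normal(0, 3, 50), axis=0)
        a1, _ = cluster_profiles(df, k=5)
        a2, _ = cluster_profiles(scaled, k=5)
        pd.testing.assert_series_equal(a1, a2)

    def test_zero_variance_profile_excluded(self):
        rng = np.random.default_rng(11)
        prof = archetype_profiles(6, 5)
        rows = {f"g{i}": prof[i % 5] + rng.normal(0, 0.1, 6) for i in range(10)}
        rows["flat"] = np.zeros(6)
        with pytest.warns(UserWarning, match="zero-variance"):
            assign, _ = cluster_profiles(pd.DataFrame.from_dict(rows, orient="index"), k=5)
        assert "flat" not in assign.index


class TestReport:
    PAIRS = pd.DataFrame(
        [
            {"gene1": "a1", "gene2": "a2", "orthogroup": "OGa"},
            {"gene1": "b1", "gene2": "b2", "orthogroup": "OGb"},
            {"gene1": "c1", "gene2": "c2", "orthogroup": "OGc"},
        ]
    )

    def test_mode_definitions(self):
        sig = pd.Series({"a1": True, "a2": False, "b1": True, "b2": True,
                         "c1": False, "c2": False})
        clusters = pd.Series({"b1": 1, "b2": 3})
        rep = pair_divergence_report(self.PAIRS, gene_significance={"timecourse": sig},
                                     clusters=clusters)
        modes = dict(zip(rep.pair, rep["mode"]))
        assert modes == {"OGa": "one-copy-regulated", "OGb": "different-dynamics",
                         "OGc": "none"}

    def test_both_modes_across_assays(self):
        sig_tc = pd.Series({"a1": True, "a2": False})
        sig_sw = pd.Series({"a1": True, "a2": True})
        clusters = pd.Series({"a1": 1, "a2": 2})
        rep = pair_divergence_report(
            self.PAIRS.iloc[:1], gene_significance={"timecourse": sig_tc, "sw": sig_sw},
            clusters=clusters,
        )
        assert rep["mode"].iloc[0] == "both"

    def test_recovers_planted_divergent_pairs(self):
        import ohnodiverge as od
        from ohnodiverge import destats, exprio

        cfg = od.SimulationConfig(seed=31, n_orthogroups=120, p_loss_post_wgd=0.3,
                                  design="smolt", n_replicates=6)
        _, truth = od.simdata.simulate_gene_trees(cfg)
        bundle = od.simdata.simulate_expression(cfg, truth)
        bundle.norm_factors = exprio.tmm_factors(bundle)
        tc = destats.timecourse_table(bundle)
        sig = tc.set_index("gene")["significant"]
        kept, filt = exprio.filter_low_expression(exprio.cpm(bundle))
        stage_means = (
            filt.loc[filt.index.intersection(tc.loc[tc.significant, "gene"])]
            .T.groupby(bundle.meta["time"]).mean().T
        )
        assign, _ = cluster_profiles(stage_means, k=5)
        pairs_df = pd.DataFrame(truth.true_pairs)
        rep = pair_divergence_report(pairs_df, gene_significance={"timecourse": sig},
                                     clusters=assign)
        called = set(rep.loc[rep["mode"] != "none", "pair"])
        planted = set(truth.divergent_pairs)
        # every planted divergent pair is recovered; the only extras
        # permitted are pair-level echoes of DE false positives, whose
        # expected count at FDR 0.01 over ~230 genes is ~1
        assert planted <= called
        assert len(called - planted) <= 2
        modes = dict(zip(rep.pair, rep["mode"]))
        for og, mode in truth.divergent_pairs.items():
            if mode == "one-copy-regulated":
                assert modes[og] in ("one-copy-regulated", "both")
            else:
                assert modes[og] in ("different-dynamics", "both")
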