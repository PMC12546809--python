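"""Protocol simulation, statistics, and report tables."""

import numpy as np
import pandas as pd
import pytest

from cogtrain import reference
from cogtrain.experiment import (CohortResults, ProtocolConfig,
                                 correlate_markers, default_protocol_cohort_spec,
                                 effect_size_d, improvement_pct, make_tables,
                                 rm_anova, round_half_up, run_protocol)
from cogtrain.profiles import make_cohort
from cogtrain.reference import (EF_BENCHMARK, NEURAL_BENCHMARK, TC_BENCHMARK,
                                EF_DOMAINS, TC_DOMAINS)


def benchmark_results(with_markers: bool = False) -> CohortResults:
    """CohortResults carrying the published benchmark pre/post values."""
    rows = []
    for domain, pairs in EF_BENCHMARK.items():
        for i, (pre, post) in enumerate(pairs):
            rows.append({"profile": f"Model_{i + 1:03d}",
                         "condition": "collaborative", "domain": domain,
                         "domain_group": "ef", "pre": pre, "post": post,
                         "improvement_pct": 100 * (post - pre) / pre})
    for domain in TC_DOMAINS:
        pre, post = TC_BENCHMARK[domain]
        for i in range(12):
            rows.append({"profile": f"Model_{i + 1:03d}",
                         "condition": "collaborative", "domain": domain,
                         "domain_group": "tc", "pre": pre, "post": post,
                         "improvement_pct": 100 * (post - pre) / pre})
    markers = None
    if with_markers:
        mrows = []
        for (region, band), (pre, post) in NEURAL_BENCHMARK.items():
            for i in range(12):
                mrows.append({"profile": f"Model_{i + 1:03d}",
                              "region": region, "band": band,
                              "pre_power": pre, "post_power": post,
                              "change_pct": 100 * (post - pre) / pre})
        markers = pd.DataFrame(mrows)
    return CohortResults(records=pd.DataFrame(rows), neural_markers=markers,
                         controller_log=pd.DataFrame(), meta={})


class TestImprovementPct:
    @pytest.mark.parametrize("pre,post,expected", [
        (72.4, 89.3, 23.3),   # benchmark WM first profile
        (68.7, 89.6, 30.4),   # benchmark strategic planning
        (50.0, 50.0, 0.0),
    ])
    def test_hand_values(self, pre, post, expected):
        assert improvement_pct(pre, post) == expected

    def test_half_up_rounding(self):
        assert improvement_pct(100.0, 123.45) == 23.5
        assert round_half_up(-1.25, 1) == -1.3  # away from zero

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            improvement_pct(0.0, 10.0)

    def test_raw_value_recomputable(self):
        raw = improvement_pct(72.4, 89.3, ndigits=None)
        assert raw == pytest.approx(100 * (89.3 - 72.4) / 72.4, abs=1e-12)


class TestEffectSize:
    def test_null_effect_zero(self):
        x = np.array([3.0, 4.0, 5.0])
        assert effect_size_d(x, x, "paired") == 0.0
        assert effect_size_d(x, x, "pooled") == 0.0

    def test_constant_shift_degenerate_paired(self):
        pre = np.array([1.0, 2.0, 3.0])
        assert np.isnan(effect_size_d(pre, pre + 1.0, "paired"))

    def test_paired_hand_value(self):
        pre = np.array([10.0, 12.0, 14.0, 16.0])
        post = np.array([13.0, 15.0, 18.0, 20.0])
        d = effect_size_d(pre, post, "paired")
        diffs = post - pre
        assert d == pytest.approx(diffs.mean() / diffs.std(ddof=1))
        assert d == pytest.approx(6.06, abs=0.01)

    def test_pooled_variant(self):
        rng = np.random.default_rng(0)
        pre = rng.normal(50, 5, 40)
        post = rng.normal(55, 5, 40)
        d = effect_size_d(pre, post, "pooled")
        pooled_sd = np.sqrt((pre.var(ddof=1) + post.var(ddof=1)) / 2)
        assert d == pytest.approx((post.mean() - pre.mean()) / pooled_sd)


class TestRMAnova:
    def _hand_oracle(self, Y):
        """Textbook sums-of-squares for a fully within a x b design,
        written as explicit loops."""
        n, a, b = Y.shape
        gm = Y.mean()
        ss_a = sum(n * b * 0 for _ in ())  # placeholder for clarity
        m_a = [Y[:, i, :].mean() for i in range(a)]
        m_b = [Y[:, :, j].mean() for j in range(b)]
        m_s = [Y[s].mean() for s in range(n)]
        ss_a = n * b * sum((m - gm) ** 2 for m in m_a)
        ss_b = n * a * sum((m - gm) ** 2 for m in m_b)
        ss_ab = 0.0
        for i in range(a):
            for j in range(b):
                ss_ab += n * (Y[:, i, j].mean() - m_a[i] - m_b[j] + gm) ** 2
        ss_as = 0.0
        for i in range(a):
            for s in range(n):
                ss_as += b * (Y[s, i, :].mean() - m_a[i] - m_s[s] + gm) ** 2
        ss_bs = 0.0
        for j in range(b):
            for s in range(n):
                ss_bs += a * (Y[s, :, j].mean() - m_b[j] - m_s[s] + gm) ** 2
        ss_tot = ((Y - gm) ** 2).sum()
        ss_sub = a * b * sum((m - gm) ** 2 for m in m_s)
        ss_abs = ss_tot - ss_sub - ss_a - ss_b - ss_ab - ss_as - ss_bs
        f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
        f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
        f_ab = (ss_ab / ((a - 1) * (b - 1))) / (
            ss_abs / ((a - 1) * (b - 1) * (n - 1)))
        return f_a, f_b, f_ab

    @staticmethod
    def _long(Y):
        n, a, b = Y.shape
        rows = []
        for s in range(n):
            for i in range(a):
                for j in range(b):
                    rows.append({"profile": s, "condition": f"c{i}",
                                 "domain": f"d{j}",
                                 "improvement_pct": Y[s, i, j]})
        return pd.DataFrame(rows)

    def test_matches_hand_oracle_2x2x4(self, rng):
        Y = rng.normal(50, 10, size=(4, 2, 2))
        res = rm_anova(self._long(Y))
        f_a, f_b, f_ab = self._hand_oracle(Y)
        assert res["condition"]["F"] == pytest.approx(f_a, abs=1e-8)
        assert res["domain"]["F"] == pytest.approx(f_b, abs=1e-8)
        assert res["interaction"]["F"] == pytest.approx(f_ab, abs=1e-8)
        assert res["condition"]["df"] == (1, 3)
        assert res["interaction"]["df"] == (1, 3)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        Y = rng.normal(0, 1, size=(8, 3, 3))
        df = self._long(Y)
        ours = rm_anova(df)
        theirs = pingouin.rm_anova(data=df, dv="improvement_pct",
                                   within=["condition", "domain"],
                                   subject="profile")
        by_source = {row.Source: row.F for row in theirs.itertuples()}
        assert ours["condition"]["F"] == pytest.approx(
            by_source["condition"], rel=1e-6)
        assert ours["domain"]["F"] == pytest.approx(
            by_source["domain"], rel=1e-6)
        assert ours["interaction"]["F"] == pytest.approx(
            by_source["condition * domain"], rel=1e-6)

    def test_identical_scores_flagged(self):
        Y = np.full((4, 2, 2), 7.0)
        res = rm_anova(self._long(Y))
        assert np.isnan(res["condition"]["F"])

    def test_unbalanced_rejected(self):
        df = self._long(np.zeros((3, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(df)

    def test_bonferroni_posthoc_present(self, rng):
        Y = rng.normal(0, 1, size=(6, 3, 2))
        res = rm_anova(self._long(Y))
        assert len(res["posthoc"]) == 3
        for c in res["posthoc"]:
            assert c["p_bonferroni"] >= c["p_raw"]


class TestCorrelations:
    def _results(self, marker_vals, improvements):
        n = len(marker_vals)
        profiles = [f"P{i}" for i in range(n)]
        rows = [{"profile": p, "condition": "collaborative",
                 "domain": "working_memory", "domain_group": "ef",
                 "pre": 50.0, "post": 50.0 * (1 + imp / 100),
                 "improvement_pct": imp}
                for p, imp in zip(profiles, improvements)]
        mrows = [{"profile": p, "region": "frontal_fz", "band": "theta",
                  "pre_power": 10.0, "post_power": 10.0 * (1 + mv / 100),
                  "change_pct": mv}
                 for p, mv in zip(profiles, marker_vals)]
        return CohortResults(records=pd.DataFrame(rows),
                             neural_markers=pd.DataFrame(mrows),
                             controller_log=pd.DataFrame(), meta={})

    def test_affine_marker_perfect_correlation(self):
        imp = [10.0, 12.0, 15.0, 18.0, 25.0]
        res = self._results([2 * v + 1 for v in imp], imp)
        corr = correlate_markers(res)
        assert corr.iloc[0]["r"] == pytest.approx(1.0)

    def test_hand_dataset_matches_closed_form(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        res = self._results(list(x), list(y))
        r = correlate_markers(res).iloc[0]["r"]
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_marker_flagged(self):
        res = self._results([5.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert np.isnan(correlate_markers(res).iloc[0]["r"])

    def test_independent_null_correlation(self, rng):
        n = 10_000
        res = self._results(list(rng.normal(20, 5, n)),
                            list(rng.normal(20, 5, n)))
        assert abs(correlate_markers(res).iloc[0]["r"]) < 0.03


class TestRunProtocol:
    def test_control_condition_no_change_noise_free(self, small_cohort):
        cfg = ProtocolConfig(conditions=("control",), noise_free=True,
                             include_neural=False, seed=1)
        res = run_protocol(small_cohort, cfg)
        assert np.allclose(res.records["improvement_pct"], 0.0)

    def test_seed_determinism(self, small_cohort):
        cfg = ProtocolConfig(seed=9, include_neural=True)
        a = run_protocol(small_cohort, cfg)
        b = run_protocol(small_cohort, ProtocolConfig(seed=9,
                                                      include_neural=True))
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.neural_markers, b.neural_markers)

    def test_condition_ordering_noise_free_strict(self, small_cohort):
        cfg = ProtocolConfig(noise_free=True, include_neural=False, seed=2)
        res = run_protocol(small_cohort, cfg)
        mean_ef = {c: res.records[
            (res.records.condition == c)
            & (res.records.domain_group == "ef")].improvement_pct.mean()
            for c in cfg.conditions}
        assert (mean_ef["collaborative"] > mean_ef["isolated_ef"]
                > mean_ef["control"])

    def test_collaborative_beats_isolated_paired_by_seed(self, small_cohort):
        cfg = ProtocolConfig(include_neural=False, seed=17)
        res = run_protocol(small_cohort, cfg)
        rec = res.records
        ef = rec[rec.domain_group == "ef"]
        assert (ef[ef.condition == "collaborative"].improvement_pct.mean()
                >= ef[ef.condition == "isolated_ef"].improvement_pct.mean())

    def test_improvement_recomputable_from_pre_post(self, small_cohort):
        cfg = ProtocolConfig(include_neural=False, seed=3)
        res = run_protocol(small_cohort, cfg)
        recomputed = 100 * (res.records.post - res.records.pre) \
            / res.records.pre
        assert np.allclose(recomputed, res.records.improvement_pct,
                           atol=0.05)

    def test_calibration_recovery_large_cohort(self):
        # configured effect targets are recovered within one point at
        # n = 500 (sampling-error bound)
        cohort = make_cohort(default_protocol_cohort_spec(n=500, seed=4))
        cfg = ProtocolConfig(conditions=("collaborative",),
                             include_neural=False, seed=4)
        res = run_protocol(cohort, cfg)
        means = res.improvements("collaborative").mean()
        for domain, target in reference.DEFAULT_EFFECT_TARGETS.items():
            assert abs(means[domain] - 100 * target) < 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            run_protocol([], ProtocolConfig())

    def test_controller_log_difficulty_in_range(self, small_cohort):
        cfg = ProtocolConfig(conditions=("collaborative",),
                             include_neural=False, seed=5)
        res = run_protocol(small_cohort, cfg)
        assert res.controller_log.difficulty.between(1, 5).all()
        assert set(res.controller_log.feedback).issubset(
            {"reward_tone", "visual_gauge", "difficulty_hint"})


class TestMakeTables:
    def test_benchmark_summary_row(self):
        # feeding the published per-profile WM values reproduces the
        # printed summary: mean pre 74.3, SD 2.6, improvement 20.4, SD 2.7
        rep = make_tables(benchmark_results())
        mean = rep.table4[rep.table4.profile == "Mean"].iloc[0]
        sd = rep.table4[rep.table4.profile == "SD"].iloc[0]
        assert round_half_up(mean["wm_pre"]) == 74.3
        assert round_half_up(sd["wm_pre"]) == 2.6
        assert mean["wm_improvement_pct"] == 20.4
        assert round_half_up(sd["wm_improvement_pct"]) == 2.7
        assert round_half_up(mean["wm_post"]) == 89.4

    def test_self_consistency_of_generated_tables(self, small_cohort):
        cfg = ProtocolConfig(include_neural=True, seed=6)
        res = run_protocol(small_cohort, cfg)
        rep = make_tables(res)
        body = rep.table4[~rep.table4.profile.isin(["Mean", "SD"])]
        for prefix in ("wm", "ic", "cf"):
            for _, row in body.iterrows():
                assert row[f"{prefix}_improvement_pct"] == improvement_pct(
                    row[f"{prefix}_pre"], row[f"{prefix}_post"])
        for _, row in rep.table5.iterrows():
            assert row["improvement_pct"] == improvement_pct(row["pre"],
                                                             row["post"])
        for _, row in rep.table6.iterrows():
            assert row["change_rate_pct"] == improvement_pct(
                row["pre_power"], row["post_power"])

    def test_benchmark_neural_change_rates(self):
        rep = make_tables(benchmark_results(with_markers=True))
        rates = rep.table6.set_index(["region", "band"])["change_rate_pct"]
        assert rates[("frontal_fz", "theta")] == 27.4
        assert rates[("parieto_occipital", "alpha")] == 19.1

    def test_effect_sizes_both_variants(self, small_cohort):
        cfg = ProtocolConfig(include_neural=False, seed=7)
        rep = make_tables(run_protocol(small_cohort, cfg))
        assert set(rep.effect_sizes.variant) == {"paired", "pooled"}
        wm = rep.effect_sizes[rep.effect_sizes.domain == "working_memory"]
        assert (wm.d > 0).all()

    def test_missing_condition_rejected(self):
        res = benchmark_results()
        with pytest.raises(ValueError):
            make_tables(res, condition="control")


def test_cli_simulate_and_report(tmp_path):
    from click.testing import CliRunner
    from cogtrain.cli import main
    runner = CliRunner()
    out = tmp_path / "run"
    result = runner.invoke(main, ["simulate", "--seed", "1", "--out",
                                  str(out)])
    assert result.exit_code == 0, result.output
    for name in ("cohort.csv", "records.csv", "run_meta.json"):
        assert (out / name).exists()
    rep = tmp_path / "rep"
    result = runner.invoke(main, [
        "evaluate", "--in", str(out / "records.csv"),
        "--markers", str(out / "neural_markers.csv"), "--out", str(rep)])
    assert result.exit_code == 0, result.output
    assert (rep / "table4.csv").exists()
    assert (rep / "anova.json").exists()


def test_config_loader_roundtrip(tmp_path):
    from cogtrain.config import load_config
    cfg_file = tmp_path / "run.yaml"
    cfg_file.write_text(
        "cohort:\n  n: 6\n  cv_range: [0.1, 0.2]\n"
        "protocol:\n  weeks: 4\n  conditions: [collaborative, control]\n")
    cohort_spec, protocol = load_config(cfg_file, seed=11)
    assert cohort_spec.n == 6 and cohort_spec.seed == 11
    assert protocol.weeks == 4 and protocol.seed == 11
    assert protocol.conditions == ("collaborative", "control")
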