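"""Assessment statistics: expected expression, LOD, titration, accuracy, precision."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpcrbench import (
    classify_features,
    complete_features_table,
    expected_expression,
    expression_comparison,
    expression_set_from_truth,
    limit_of_detection,
    precision_summary,
    quality_summary,
    signal_detect_slopes,
    titration_response,
)
from qpcrbench.assess import CATEGORIES
from qpcrbench.datamodel import AlignmentError

from conftest import make_expression_set


def _full_design_es(rng, n_features=20, missing_rate=0.0, poor_rate=0.0, name="toy"):
    """Random ExpressionSet over the full 10x4 sample layout."""
    cols = [f"{t}:{r}" for t in range(1, 11) for r in range(1, 5)]
    expr = pd.DataFrame(
        rng.uniform(15, 35, size=(n_features, len(cols))),
        index=[f"feat{i}" for i in range(n_features)],
        columns=cols,
    )
    qual = pd.DataFrame(1.0, index=expr.index, columns=expr.columns)
    if poor_rate:
        qual = qual.mask(rng.random(qual.shape) < poor_rate, 0.5)
    if missing_rate:
        expr = expr.mask(rng.random(expr.shape) < missing_rate)
    from qpcrbench import ExpressionSet

    return ExpressionSet(method_name=name, expression=expr, quality=qual)


class TestExpectedExpression:
    def test_pure_weight_returns_pure_value(self):
        assert expected_expression(23.4, 30.0, 1.0, 0.0) == pytest.approx(23.4, abs=1e-12)

    def test_equal_pools_tenth_dilution(self):
        # E_A = E_B = 20, weights (0.1, 0.1): 20 - log2(0.2)
        assert expected_expression(20.0, 20.0, 0.1, 0.1) == pytest.approx(20.0 + math.log2(5), abs=1e-9)

    def test_tenfold_dilution_shifts_by_log2_ten(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            ea, eb = rng.uniform(12, 38, 2)
            wa, wb = rng.uniform(0.05, 1.0, 2)
            base = expected_expression(ea, eb, wa, wb)
            diluted = expected_expression(ea, eb, 0.1 * wa, 0.1 * wb)
            assert diluted - base == pytest.approx(math.log2(10), abs=1e-9)

    def test_missing_and_absent_pure_values(self):
        assert math.isnan(expected_expression(float("nan"), 20.0, 0.5, 0.5))
        # absent-in-pool (inf) contributes zero abundance
        assert expected_expression(float("inf"), 20.0, 0.5, 0.5) == pytest.approx(21.0)
        with pytest.raises(ValueError):
            expected_expression(20.0, 20.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        ea=st.floats(10.0, 40.0),
        eb=st.floats(10.0, 40.0),
        wa=st.floats(0.01, 1.0),
        wb=st.floats(0.01, 1.0),
    )
    def test_mixture_bounds_and_monotonicity(self, ea, eb, wa, wb):
        """A mixture is at least as abundant as its strongest weighted part
        and adding material only increases abundance (decreases cycles)."""
        e = expected_expression(ea, eb, wa, wb)
        assert e <= min(ea - math.log2(wa), eb - math.log2(wb)) + 1e-9
        assert e >= min(ea, eb) - math.log2(wa + wb) - 1e-9
        assert expected_expression(ea, eb, wa * 2, wb) < e

    def test_series_input_preserves_index(self):
        s = pd.Series([20.0, 25.0], index=["a", "b"])
        out = expected_expression(s, s, 0.5, 0.5)
        assert list(out.index) == ["a", "b"]
        assert out["a"] == pytest.approx(20.0)


class TestClassifyAndCrosstab:
    def test_all_good_toy_set_is_complete(self):
        es = make_expression_set({"1:1": [20, 21, 22], "1:2": [20, 21, 22]})
        assert (classify_features(es) == "complete").all()

    def test_categories_partition_random_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            es = _full_design_es(rng, missing_rate=0.3, poor_rate=0.3)
            counts = classify_features(es).value_counts()
            assert int(counts.sum()) == 20
            assert set(counts.index) <= set(CATEGORIES)

    def test_crosstab_margins_and_total(self):
        rng = np.random.default_rng(29)
        es1 = _full_design_es(rng, missing_rate=0.2, poor_rate=0.2, name="m1")
        es2 = _full_design_es(rng, missing_rate=0.2, poor_rate=0.2, name="m2")
        tab = complete_features_table(es1, es2)
        assert tab.grand_total == 20
        c1 = classify_features(es1).value_counts()
        c2 = classify_features(es2).value_counts()
        for cat in CATEGORIES:
            assert tab.margins1[cat] == c1.get(cat, 0)
            assert tab.margins2[cat] == c2.get(cat, 0)

    def test_identical_inputs_give_diagonal_table(self):
        rng = np.random.default_rng(31)
        es = _full_design_es(rng, missing_rate=0.3, poor_rate=0.3)
        tab = complete_features_table(es, es).table
        off_diag = tab.to_numpy().sum() - np.trace(tab.to_numpy())
        assert off_diag == 0


class TestExpressionComparison:
    def test_identical_sets_have_no_flags(self):
        rng = np.random.default_rng(37)
        es = _full_design_es(rng)
        res = expression_comparison(es, es, delta_threshold=2.0)
        assert len(res.flagged) == 0
        assert len(res.pairs) == 20 * 40

    def test_single_perturbed_entry_is_the_only_flag(self):
        rng = np.random.default_rng(41)
        es1 = _full_design_es(rng, name="m1")
        expr2 = es1.expression.copy()
        expr2.iloc[3, 7] += 4.0  # 2x the threshold
        from qpcrbench import ExpressionSet

        es2 = ExpressionSet("m2", expr2, es1.quality.copy())
        res = expression_comparison(es1, es2, delta_threshold=2.0)
        assert len(res.flagged) == 1
        assert res.flagged.iloc[0]["feature_id"] == "feat3"

    def test_restriction_to_jointly_good_entries(self):
        rng = np.random.default_rng(43)
        es1 = _full_design_es(rng, poor_rate=0.5, name="m1")
        es2 = _full_design_es(rng, name="m2")
        res = expression_comparison(es1, es2)
        good1 = es1.good_quality().to_numpy().sum()
        assert len(res.pairs) == good1  # es2 all good

    def test_axis_mismatch_raises(self):
        rng = np.random.default_rng(47)
        es1 = _full_design_es(rng)
        es2 = _full_design_es(rng, n_features=19)
        with pytest.raises(AlignmentError):
            expression_comparison(es1, es2)


class TestLimitOfDetection:
    def _constructed_step(self, breakpoint=28.0):
        """Observed type-9/10 values whose type10-vs-type9 differences are a
        step function of the expected expression: 0 below the breakpoint, 2
        at and above it (one feature at the breakpoint)."""
        base = [18.0, 19.0, 20.0, 21.0, 22.0, 23.0, 24.0, 25.0, 26.0, 27.0, breakpoint]
        shift = math.log2(10)
        cols = {}
        for t in range(1, 11):
            for r in range(1, 5):
                if t == 9:
                    cols[f"{t}:{r}"] = [v - shift for v in base]
                elif t == 10:
                    cols[f"{t}:{r}"] = [v if v < breakpoint else v + 2.0 for v in base]
                else:
                    cols[f"{t}:{r}"] = base
        return make_expression_set(cols)

    def test_constructed_step_recovers_breakpoint_exactly(self, design):
        es = self._constructed_step(28.0)
        res = limit_of_detection(es, design, tolerances=(1.5, 2.0))
        for tol in (1.5, 2.0):
            assert res.thresholds.loc["type10_vs_type9", tol] == 28.0

    def test_tolerance_beyond_max_difference_is_missing(self, design):
        es = self._constructed_step(28.0)
        res = limit_of_detection(es, design, tolerances=(5.0,))
        assert math.isnan(res.thresholds.loc["type10_vs_type9", 5.0])

    def test_thresholds_non_decreasing_in_tolerance(self, design, noisy_truth_es):
        res = limit_of_detection(noisy_truth_es, design, tolerances=(0.05, 0.1, 0.2, 0.4))
        for _, row in res.thresholds.iterrows():
            vals = [v for v in row.to_list() if not pd.isna(v)]
            assert vals == sorted(vals)

    def test_signed_difference_definition(self, design):
        es = self._constructed_step(28.0)
        res = limit_of_detection(es, design)
        sub = res.per_feature[res.per_feature["comparison"] == "type10_vs_type9"].dropna()
        np.testing.assert_allclose(
            sub["difference"], sub["observed"] - sub["expected"], atol=1e-12
        )

    def test_proportion_poor_quality_levels(self, design):
        es = self._constructed_step(28.0)
        es.quality.loc["feat1", ["10:1", "10:2"]] = 0.0  # two poor replicates
        res = limit_of_detection(es, design)
        sub = res.per_feature.query("comparison == 'type10_vs_type9'").set_index("feature_id")
        assert sub.loc["feat1", "proportion_poor_quality"] == pytest.approx(0.5)
        assert set(np.round(sub["proportion_poor_quality"], 3)) <= {0.0, 0.25, 0.5, 0.75, 1.0}


class TestTitrationResponse:
    def test_monotone_and_tied_features(self, design):
        # feat1 responds in series B (types 2-4); feat2 has a tie
        cols = {}
        for t in range(1, 11):
            for r in range(1, 5):
                v1 = {2: 28.0, 3: 27.0, 4: 26.0}.get(t, 24.0)
                v2 = {2: 28.0, 3: 28.0, 4: 26.0}.get(t, 24.0)
                cols[f"{t}:{r}"] = [v1, v2]
        es = make_expression_set(cols)
        res = titration_response(es, design)
        pf = res.per_feature.set_index(["series", "feature_id"])
        assert pf.loc[("B", "feat1"), "responder"]
        assert not pf.loc[("B", "feat2"), "responder"]

    def test_noise_free_simulation_titratable_features_all_respond(
        self, design, noisefree_sim
    ):
        truth, _, table = noisefree_sim
        es = expression_set_from_truth(table)
        res = titration_response(es, design)
        ev = res.per_feature[res.per_feature["evaluable"]]
        pure = truth.table.set_index("feature_id")
        for series, col in (("A", "ct_a"), ("B", "ct_b")):
            sub = ev[ev["series"] == series]
            titratable = sub["feature_id"].map(pure[col].notna())
            assert sub[titratable]["responder"].all()
            assert not sub[~titratable]["responder"].any()

    def test_stratum_sign_convention(self, design, noisefree_sim):
        """d > 0 iff the titrated component is the more abundant one."""
        truth, _, table = noisefree_sim
        es = expression_set_from_truth(table)
        res = titration_response(es, design)
        pure = truth.table.set_index("feature_id")
        sub = res.per_feature.query("series == 'A'").dropna(subset=["d"]).set_index("feature_id")
        expected_d = pure["ct_b"] - pure["ct_a"]
        joined = sub.join(expected_d.rename("want"), how="inner").dropna(subset=["want"])
        np.testing.assert_allclose(joined["d"], joined["want"], atol=1e-12)


class TestSignalDetectSlopes:
    def test_noisy_recovery_median_slope_near_one(self, design, noisy_truth_es):
        res = signal_detect_slopes(noisy_truth_es, design)
        med = res.per_feature["slope"].median()
        assert 0.9 <= med <= 1.1

    def test_constant_observed_gives_zero_nonsignificant_slope(self, design):
        cols = {f"{t}:{r}": [24.0, 20.0] for t in range(1, 11) for r in range(1, 5)}
        es = make_expression_set(cols)
        res = signal_detect_slopes(es, design)
        sub = res.per_feature.dropna(subset=["slope"])
        assert np.allclose(sub["slope"], 0.0)
        assert not sub["significant"].any()

    def test_too_few_points_gives_missing_slope(self, design):
        cols = {f"{t}:{r}": [24.0] for t in range(1, 11) for r in range(1, 5)}
        es = make_expression_set(cols)
        es.quality.loc[:, [c for c in es.quality.columns if c.startswith(("6:", "7:"))]] = 0.0
        # series A now has only type-8 points with a single expected value
        res = signal_detect_slopes(es, design)
        assert math.isnan(res.per_feature.set_index("series").loc["A", "slope"])

    def test_summary_bins_are_tertiles(self, design, noisy_truth_es):
        res = signal_detect_slopes(noisy_truth_es, design)
        sizes = res.summary["n"].to_numpy()
        assert len(sizes) == 3
        assert sizes.max() - sizes.min() <= 2


class TestPrecision:
    def test_hand_computed_sd_and_cv(self):
        cols = {f"1:{r}": [v] for r, v in zip(range(1, 5), (19.0, 20.0, 21.0, 20.0))}
        es = make_expression_set(cols)
        res = precision_summary(es)
        row = res.per_group.iloc[0]
        assert row["sd"] == pytest.approx(0.816497, abs=1e-6)
        assert row["cv"] == pytest.approx(0.040825, abs=1e-6)

    def test_identical_replicates_have_zero_spread(self):
        cols = {f"1:{r}": [20.0] for r in range(1, 5)}
        res = precision_summary(make_expression_set(cols))
        assert res.per_group.iloc[0]["sd"] == 0.0
        assert res.per_group.iloc[0]["cv"] == 0.0

    def test_replicate_order_invariance(self):
        vals = [18.5, 22.0, 20.5, 19.0]
        a = precision_summary(
            make_expression_set({f"1:{r}": [v] for r, v in zip(range(1, 5), vals)})
        )
        b = precision_summary(
            make_expression_set({f"1:{r}": [v] for r, v in zip(range(1, 5), vals[::-1])})
        )
        assert a.per_group.iloc[0]["sd"] == b.per_group.iloc[0]["sd"]
        assert a.per_group.iloc[0]["cv"] == b.per_group.iloc[0]["cv"]

    def test_group_filtering_rules(self):
        rng = np.random.default_rng(53)
        es = _full_design_es(rng, n_features=2)
        es.quality.loc["feat0", "3:2"] = 0.5      # one poor replicate: group dropped
        es.expression.loc["feat1", ["4:1", "4:2", "4:3"]] = np.nan  # single present
        res = precision_summary(es)
        keys = set(zip(res.per_group["feature_id"], res.per_group["sample_type"]))
        assert ("feat0", 3) not in keys
        assert ("feat1", 4) not in keys
        assert ("feat0", 4) in keys

    def test_oracle_equivalence_two_pass(self, noisy_truth_es):
        """SD/CV match a brute-force two-pass computation on every group."""
        res = precision_summary(noisy_truth_es)
        expr = noisy_truth_es.expression
        for _, row in res.per_group.sample(200, random_state=0).iterrows():
            cols = noisy_truth_es.columns_of_type(int(row["sample_type"]))
            vals = [v for v in expr.loc[row["feature_id"], cols] if not pd.isna(v)]
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            assert row["mean"] == pytest.approx(mean, abs=1e-12)
            assert row["sd"] == pytest.approx(sd, abs=1e-12)
            assert row["cv"] == pytest.approx(sd / mean, abs=1e-12)


class TestQualitySummary:
    def test_missing_entries_concentrate_at_zero_quality(self):
        rng = np.random.default_rng(59)
        es = _full_design_es(rng, missing_rate=0.2)
        es.quality = es.quality.where(es.expression.notna(), 0.0)
        res = quality_summary(es)
        assert (res.missing_quality == 0.0).all()
        assert len(res.present) + len(res.missing_quality) == 20 * 40

    def test_quality_declines_with_expression_on_noisy_fits(self):
        """Later (lower-abundance) curves earn lower fit quality."""
        from qpcrbench import NoiseConfig, estimate_expression, generate_truth, simulate_benchmark
        from qpcrbench.simulate import TruthConfig

        truth = generate_truth(30, TruthConfig(ct_range=(16.0, 36.0)), seed=61)
        noise = NoiseConfig(seed=62, failure_rate=0.0, dropout_expression_midpoint=None)
        dataset, table = simulate_benchmark(truth, noise=noise)
        es = estimate_expression(dataset, "b4")
        true_ct = table.set_index(["feature_id", "sample_id"])["true_ct"]
        qual = es.quality.stack(future_stack=True)
        early = [qual.loc[k] for k, v in true_ct.items() if 18 <= v <= 24]
        late = [qual.loc[k] for k, v in true_ct.items() if 30 <= v <= 36]
        assert np.median(late) < np.median(early)
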