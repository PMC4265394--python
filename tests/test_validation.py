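"""Calibration, goodness of fit, ROC/AUC and the DeLong comparison."""

import json
from collections import OrderedDict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predictebc import (
    Cohort,
    RiskPrediction,
    calibration_table,
    delong_test,
    observed_outcomes,
    quantile_gof,
    roc_auc,
    strata_by_quantile,
    validation_report,
)
from predictebc.validation import poisson_ci

from conftest import make_record


def fake_prediction(pid: str, cuminc10: float, version: str = "v3") -> RiskPrediction:
    """A hand-built prediction whose 10-year cumulative mortality is given."""
    cum = np.linspace(0.0, cuminc10, 11)
    ones = np.ones(11)
    return RiskPrediction(
        id=pid, version=version, s_bc=1 - cum, s_oc=ones.copy(),
        overall=1 - cum, cuminc_bc=cum, cuminc_oc=np.zeros(11),
    )


class TestObservedOutcomes:
    @pytest.mark.parametrize("outcome,t,expected", [
        ("bc_death", 4.2, "event"),
        ("bc_death", 10.0, "event"),
        ("bc_death", 11.0, "non_event"),
        ("other_death", 3.0, "competing"),
        ("other_death", 12.0, "non_event"),
        ("censored", 6.0, "censored"),
        ("censored", 10.0, "non_event"),
        ("censored", 14.0, "non_event"),
    ])
    def test_rule_table(self, outcome, t, expected):
        cohort = Cohort([make_record(outcome=outcome, follow_up_years=t)])
        assert observed_outcomes(cohort, 10.0) == [expected]

    def test_nonpositive_horizon_rejected(self, cohort6):
        with pytest.raises(ValueError):
            observed_outcomes(cohort6, 0.0)


class TestCalibration:
    def _cohort(self, outcomes):
        return Cohort([
            make_record(id=f"p{i}", outcome=o, follow_up_years=t)
            for i, (o, t) in enumerate(outcomes)
        ])

    def test_expected_is_sum_of_predicted_mortality(self):
        cohort = self._cohort([("censored", 12.0)] * 4)
        preds = [fake_prediction(f"p{i}", c)
                 for i, c in enumerate([0.1, 0.2, 0.3, 0.4])]
        strata = OrderedDict([("all", [f"p{i}" for i in range(4)])])
        table = calibration_table(cohort, preds, preds, strata)
        assert table[0].expected_v2 == pytest.approx(1.0)
        assert table[0].n == 4

    def test_all_zero_predictions_zero_expected(self):
        cohort = self._cohort([("bc_death", 2.0), ("censored", 12.0)])
        preds = [fake_prediction("p0", 0.0), fake_prediction("p1", 0.0)]
        strata = OrderedDict([("a", ["p0"]), ("b", ["p1"])])
        table = calibration_table(cohort, preds, preds, strata)
        assert all(s.expected_v3 == 0.0 for s in table)
        assert table[0].observed_deaths == 1

    def test_additive_over_any_partition(self):
        outcomes = [("bc_death", 3.0)] * 3 + [("censored", 12.0)] * 5
        cohort = self._cohort(outcomes)
        preds = [fake_prediction(f"p{i}", 0.05 * (i + 1)) for i in range(8)]
        whole = OrderedDict([("all", [f"p{i}" for i in range(8)])])
        split = OrderedDict([("a", ["p0", "p3", "p6"]),
                             ("b", ["p1", "p2", "p4", "p5", "p7"])])
        t_whole = calibration_table(cohort, preds, preds, whole)
        t_split = calibration_table(cohort, preds, preds, split)
        assert sum(s.expected_v2 for s in t_split) == pytest.approx(
            t_whole[0].expected_v2
        )
        assert sum(s.observed_deaths for s in t_split) == t_whole[0].observed_deaths

    def test_non_partition_rejected(self):
        cohort = self._cohort([("censored", 12.0)] * 2)
        preds = [fake_prediction("p0", 0.1), fake_prediction("p1", 0.1)]
        with pytest.raises(ValueError, match="partition"):
            calibration_table(cohort, preds, preds,
                              OrderedDict([("only", ["p0"])]))

    def test_poisson_ci_exact_interval(self):
        lo, hi = poisson_ci(0)
        assert lo == 0.0 and hi == pytest.approx(3.6889, abs=1e-3)
        lo, hi = poisson_ci(10)
        assert lo == pytest.approx(4.795, abs=1e-2)
        assert hi == pytest.approx(18.39, abs=1e-2)


class TestQuantileGof:
    def _setup(self, observed_per_bin, expected_per_bin, n_per_bin=10):
        """k bins of n patients; per-bin observed deaths and expected sums."""
        recs, preds = [], []
        for b, (o, e) in enumerate(zip(observed_per_bin, expected_per_bin)):
            for j in range(n_per_bin):
                pid = f"b{b}x{j}"
                dead = j < o
                recs.append(make_record(
                    id=pid, outcome="bc_death" if dead else "censored",
                    follow_up_years=5.0 if dead else 12.0,
                ))
                # distinct scores keep bin membership deterministic
                preds.append(fake_prediction(pid, (b + 1) / 10 + e * 1e-9 + j * 1e-6))
        # rescale so each bin's expected sums to e
        bins = strata_by_quantile(preds, len(observed_per_bin))
        by_id = {p.id: p for p in preds}
        for (label, ids), e in zip(bins.items(), expected_per_bin):
            total = sum(by_id[i].cuminc_bc[10] for i in ids)
            for i in ids:
                by_id[i].cuminc_bc = by_id[i].cuminc_bc * (e / total)
        return Cohort(recs), preds

    def test_perfect_calibration_chi2_zero(self):
        cohort, preds = self._setup([2, 3], [2.0, 3.0])
        g = quantile_gof(cohort, preds, k=2)
        assert g.chi2 == pytest.approx(0.0, abs=1e-9)
        assert g.p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        cohort, preds = self._setup([2, 3], [1.0, 4.0])
        g = quantile_gof(cohort, preds, k=2, df=2)
        assert g.chi2 == pytest.approx(1.0 / 1.0 + 1.0 / 4.0)
        assert g.df == 2

    def test_doubling_counts_doubles_chi2(self):
        _, preds1 = self._setup([2, 3], [1.0, 4.0])
        c1, p1 = self._setup([2, 3], [1.0, 4.0])
        c2, p2 = self._setup([4, 6], [2.0, 8.0], n_per_bin=20)
        g1 = quantile_gof(c1, p1, k=2)
        g2 = quantile_gof(c2, p2, k=2)
        assert g2.chi2 == pytest.approx(2 * g1.chi2, rel=1e-6)

    def test_default_df_matches_bin_count(self):
        cohort, preds = self._setup([1, 1, 1, 1, 1], [1.0] * 5, n_per_bin=4)
        g = quantile_gof(cohort, preds, k=5)
        assert g.df == 5

    def test_zero_expected_with_observed_is_error(self):
        cohort, preds = self._setup([2, 3], [1.0, 4.0])
        for p in preds:
            p.cuminc_bc = p.cuminc_bc * 0.0
        with pytest.raises(ValueError, match="expected 0"):
            quantile_gof(cohort, preds, k=2)


def brute_force_auc(scores, labels):
    """Exhaustive Mann-Whitney enumeration over all (event, non-event) pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        r = roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert r.auc == 0.5

    def test_enumerated_four_pair_example(self):
        # events {0.9, 0.4}, non-events {0.5, 0.1}: 3 of 4 pairs concordant
        r = roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(4, 200))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels),
                                          abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 150)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(150), 2)
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=-5, max_value=5), min_size=4,
                    max_size=40))
    def test_invariant_under_increasing_transform(self, scores):
        # a 1e-3 grid keeps the transform strictly increasing in floats
        scores = np.round(np.asarray(scores), 3)
        labels = (np.arange(len(scores)) % 2).astype(int)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(0.5 * scores) + 3, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_curve_endpoints_and_monotone(self):
        rng = np.random.default_rng(5)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        r = roc_auc(scores, labels)
        assert tuple(r.curve[0]) == (0.0, 0.0)
        assert tuple(r.curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.curve[:, 0]) >= 0)
        assert np.all(np.diff(r.curve[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_self_comparison_degenerate(self):
        scores = [0.1, 0.9, 0.3, 0.7]
        labels = [0, 1, 0, 1]
        cmp_ = delong_test(scores, scores, labels)
        assert cmp_.delta == 0.0 and cmp_.p == 1.0 and cmp_.degenerate

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        ab = delong_test(a, b, labels)
        ba = delong_test(b, a, labels)
        assert ab.delta == pytest.approx(-ba.delta)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_variance_nonnegative_everywhere(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(4, 80))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            cmp_ = delong_test(rng.random(n), rng.random(n), labels)
            assert cmp_.var_delta >= 0.0
            assert 0.0 <= cmp_.p <= 1.0

    def test_delta_ci_covers_zero_under_null(self):
        """Paired scores differing only by symmetric noise: the 95% CI on
        delta should cover 0 at roughly nominal frequency."""
        rng = np.random.default_rng(2024)
        n, reps, covered = 120, 200, 0
        for _ in range(reps):
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            base = rng.normal(size=n) + labels  # informative scores
            a = base + 0.3 * rng.normal(size=n)
            b = base + 0.3 * rng.normal(size=n)
            cmp_ = delong_test(a, b, labels)
            half = 1.959964 * np.sqrt(cmp_.var_delta)
            covered += abs(cmp_.delta) <= half
        assert 0.90 <= covered / reps <= 0.99


class TestValidationReport:
    def test_er_negative_cohort_versions_identical(self, default_config):
        rng = np.random.default_rng(12)
        recs = [
            make_record(
                id=f"e{i}", er="neg", size_mm=float(rng.uniform(5, 50)),
                grade=float(rng.integers(0, 3)), nodes_pos=float(rng.integers(0, 12)),
                her2=float(rng.integers(0, 2)), ki67=float(rng.integers(0, 2)),
                age_dx=float(rng.uniform(35, 80)),
                follow_up_years=float(rng.uniform(0.5, 15)),
                outcome=str(rng.choice(["censored", "bc_death", "other_death"])),
            )
            for i in range(60)
        ]
        rep = validation_report(Cohort(recs), default_config)
        sub = rep["subsets"]["all"]
        assert "er_pos" not in rep["subsets"]
        assert sub["discrimination"]["auc_v2"] == sub["discrimination"]["auc_v3"]
        assert sub["gof"]["v2"] == sub["gof"]["v3"]

    def test_deterministic_and_json_serialisable(self, default_config):
        from predictebc import SimulationSpec, impute_missing, simulate_cohort

        cohort = impute_missing(simulate_cohort(SimulationSpec(n=150, seed=5)))
        r1 = validation_report(cohort, default_config)
        r2 = validation_report(cohort, default_config)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
        for key in ("calibration", "gof", "discrimination"):
            assert key in r1["subsets"]["all"]

    def test_too_few_events_degrades_gracefully(self, default_config):
        recs = [make_record(id=f"s{i}", outcome="censored",
                            follow_up_years=12.0, her2=0.0, ki67=0.0)
                for i in range(8)]
        rep = validation_report(Cohort(recs), default_config)
        assert rep["subsets"]["all"]["discrimination"]["available"] is False
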