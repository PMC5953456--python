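"""Survey simulator: questionnaire mechanics, randomizer calibration,
cheating and nonresponse machinery, and aggregation."""

import numpy as np
import pytest

from uqm import (
    SimulationConfig,
    aggregate_counts,
    estimate_prevalence,
    fit_shared_prevalence,
    fixture_study,
    lr_test,
    simulate_survey,
    yes_probability,
)
from uqm.synthetic_data import CYCLE_DAYS, VERSIONS, _CYCLE_DAY, _CYCLE_MONTH
from uqm.datasets import VERSION_COUNTS


class TestVersions:
    def test_counterbalancing_table(self):
        assert VERSIONS[1].first_item == "cognitive"
        assert VERSIONS[1].p_first == "two_thirds"
        assert VERSIONS[1].second_item == "physical"
        assert VERSIONS[1].p_second == "one_third"
        assert VERSIONS[8].first_item == "physical"
        assert VERSIONS[8].p_first == "one_third"
        assert VERSIONS[8].p_second == "two_thirds"
        # each (order, p_first, p_second) combination appears exactly once
        combos = {(v.first_item, v.p_first, v.p_second) for v in VERSIONS.values()}
        assert len(combos) == 8

    def test_cycle_calendar(self):
        assert CYCLE_DAYS == 1461
        assert (_CYCLE_DAY == 29).sum() - ((_CYCLE_MONTH == 2) & (_CYCLE_DAY == 29)).sum() == 44
        # exactly one Feb 29 per cycle
        assert ((_CYCLE_MONTH == 2) & (_CYCLE_DAY == 29)).sum() == 1
        # first half of the year: 181.25 days per year on average
        assert (_CYCLE_MONTH <= 6).sum() == 725


class TestSimulateSurvey:
    def test_reproducible_under_seed(self):
        cfg = SimulationConfig(n_respondents=500, seed=99)
        assert simulate_survey(cfg).equals(simulate_survey(cfg))

    def test_branch_fraction_matches_design(self):
        cfg = SimulationConfig(
            n_respondents=200_000, seed=5, include_truth=True,
            nonresponse_none=0.0, nonresponse_second_only=0.0,
        )
        table = simulate_survey(cfg)
        day = _CYCLE_DAY[table["birthday_day_index_first"].to_numpy() - 1]
        frac = (day >= 21).mean()
        assert frac == pytest.approx(125.25 / 365.25, abs=0.004)

    def test_empirical_yes_rate_matches_marginal(self, two_thirds):
        cfg = SimulationConfig(
            n_respondents=150_000, pi_physical=0.15, pi_cognitive=0.15,
            nonresponse_none=0.0, nonresponse_second_only=0.0, seed=17,
        )
        counts = aggregate_counts(simulate_survey(cfg))
        lam = yes_probability(two_thirds, 0.15)
        for c in counts:
            if float(c.design.p) > 0.5:
                assert c.yes / c.n == pytest.approx(lam, abs=0.005)

    def test_universal_cheating_drives_estimate_to_zero(self):
        cfg = SimulationConfig(
            n_respondents=50_000, pi_physical=0.2, pi_cognitive=0.2,
            cheating_prob_by_design={"one_third": 1.0, "two_thirds": 1.0},
            nonresponse_none=0.0, nonresponse_second_only=0.0, seed=23,
        )
        for c in aggregate_counts(simulate_survey(cfg)):
            assert estimate_prevalence(c).pi_hat == pytest.approx(0.0, abs=0.02)

    def test_design_specific_cheating_lowers_two_thirds_estimate(self):
        """The self-protection hypothesis: more cheating at larger p
        pushes the apparent prevalence under p≈2/3 below that of p≈1/3."""
        cfg = SimulationConfig(
            n_respondents=100_000, pi_physical=0.2, pi_cognitive=0.2,
            cheating_prob_by_design={"one_third": 0.1, "two_thirds": 0.5},
            nonresponse_none=0.0, nonresponse_second_only=0.0, seed=31,
        )
        ests = {
            (c.item, float(c.design.p) > 0.5): estimate_prevalence(c).pi_hat
            for c in aggregate_counts(simulate_survey(cfg))
        }
        for item in ("physical", "cognitive"):
            assert ests[(item, True)] < ests[(item, False)]

    def test_literal_single_birthday_biases_estimates_upward(self):
        """With the neutral answer tied to the routing birthday (the
        printed questionnaire), the conditional neutral-yes probability
        is exactly 1/2, inflating estimates by (1-p)/p * (1/2 - pi_n)."""
        cfg = SimulationConfig(
            n_respondents=1_000_000, pi_physical=0.15, pi_cognitive=0.15,
            nonresponse_none=0.0, nonresponse_second_only=0.0,
            neutral_same_birthday=True, seed=13,
        )
        shift = 0.5 - 725 / 1461
        for c in aggregate_counts(simulate_survey(cfg)):
            p = float(c.design.p)
            expected_bias = (1 - p) / p * shift
            observed_bias = estimate_prevalence(c).pi_hat - 0.15
            assert observed_bias == pytest.approx(expected_bias, abs=0.004)
            assert observed_bias > 0

    def test_total_nonresponse(self):
        cfg = SimulationConfig(n_respondents=200, nonresponse_none=1.0, seed=1)
        table = simulate_survey(cfg)
        assert (table["answer_first"] == "").all()
        assert (table["answer_second"] == "").all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pi_physical=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(version_weights=(1.0,) * 8)


class TestAggregateCounts:
    def test_totals_account_for_nonresponse(self):
        table, _ = fixture_study()
        counts = {c.item: 0 for c in aggregate_counts(table)}
        for c in aggregate_counts(table):
            counts[c.item] += c.n
        n_first_answered = (table["answer_first"] != "").sum()
        n_second_answered = (table["answer_second"] != "").sum()
        by_item_expected = {"physical": 0, "cognitive": 0}
        first_phys = table["version"].isin([5, 6, 7, 8])
        by_item_expected["physical"] = (
            ((table["answer_first"] != "") & first_phys).sum()
            + ((table["answer_second"] != "") & ~first_phys).sum()
        )
        by_item_expected["cognitive"] = n_first_answered + n_second_answered - by_item_expected["physical"]
        assert counts == {k: int(v) for k, v in by_item_expected.items()}

    def test_zero_nonresponse_totals_equal_n(self):
        cfg = SimulationConfig(
            n_respondents=3000, nonresponse_none=0.0, nonresponse_second_only=0.0, seed=2
        )
        totals = {}
        for c in aggregate_counts(simulate_survey(cfg)):
            totals[c.item] = totals.get(c.item, 0) + c.n
        assert totals == {"physical": 3000, "cognitive": 3000}

    def test_row_order_invariance(self):
        table, _ = fixture_study()
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = {(c.item, c.design.label): (c.yes, c.no) for c in aggregate_counts(table)}
        b = {(c.item, c.design.label): (c.yes, c.no) for c in aggregate_counts(shuffled)}
        assert a == b


class TestFixtureStudy:
    def test_byte_identical_reruns(self):
        t1, c1 = fixture_study()
        t2, c2 = fixture_study()
        assert t1.equals(t2) and c1 == c2

    def test_version_distribution_matches_study(self):
        table, _ = fixture_study()
        observed = table["version"].value_counts().sort_index().to_numpy()
        expected = np.array(VERSION_COUNTS)
        # multinomial sampling error: 3 SDs per cell
        sd = np.sqrt(expected * (1 - expected / expected.sum()))
        assert (np.abs(observed - expected) < 3 * sd + 5).all()

    def test_full_pipeline_smoke(self):
        table, _ = fixture_study()
        counts = aggregate_counts(table)
        by_item = {}
        for c in counts:
            by_item.setdefault(c.item, []).append(c)
        for item, conds in by_item.items():
            est = fit_shared_prevalence(conds)
            assert -0.1 < est.pi_hat < 0.5
            res = lr_test(*conds)
            assert 0 <= res.p_value <= 1


class TestParameterRecovery:
    def test_pipeline_recovers_true_prevalences(self):
        """Replicated honest surveys: the mean pooled estimate must sit
        within Monte-Carlo error of the configured truths."""
        reps, n = 60, 20_000
        true_phys, true_cog = 0.144, 0.188
        est_p, est_c = [], []
        for r in range(reps):
            cfg = SimulationConfig(
                n_respondents=n, pi_physical=true_phys, pi_cognitive=true_cog,
                nonresponse_none=0.0, nonresponse_second_only=0.0, seed=1000 + r,
            )
            by_item = {}
            for c in aggregate_counts(simulate_survey(cfg)):
                by_item.setdefault(c.item, []).append(c)
            est_p.append(fit_shared_prevalence(by_item["physical"]).pi_hat)
            est_c.append(fit_shared_prevalence(by_item["cognitive"]).pi_hat)
        for ests, truth in ((est_p, true_phys), (est_c, true_cog)):
            ests = np.asarray(ests)
            mc_se = ests.std(ddof=1) / np.sqrt(reps)
            assert abs(ests.mean() - truth) < 3 * mc_se
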