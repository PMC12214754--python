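"""Inclusion criteria: ANOVA, Fano slope, selectivity, reliability, BSI."""

import numpy as np
import pytest

import posexis as px
from posexis.synthetic_data import UnitRecording
from posexis.unit_selection import SelectionThresholds, spearman_brown


class TestResponsivityAnova:
    def test_matches_pingouin_mixed_anova(self):
        """Closed-form split-plot sums of squares against the reference
        mixed-ANOVA implementation on one random dataset."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        n_trials, n_stim = 5, 8
        base = rng.gamma(4.0, 2.0, (n_trials, n_stim))
        resp = rng.gamma(5.0, 2.0, (n_trials, n_stim))
        p_win, p_int = px.responsivity_anova(base, resp)

        rows = []
        for t in range(n_trials):
            for s in range(n_stim):
                subj = t * n_stim + s
                rows.append((subj, s, "baseline", base[t, s]))
                rows.append((subj, s, "response", resp[t, s]))
        df = pd.DataFrame(rows, columns=["subject", "stimulus", "window", "rate"])
        aov = pingouin.mixed_anova(
            df, dv="rate", within="window", subject="subject", between="stimulus"
        ).set_index("Source")
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        assert p_win == pytest.approx(aov.loc["window", pcol], rel=1e-8)
        assert p_int == pytest.approx(aov.loc["Interaction", pcol], rel=1e-8)

    def test_forced_window_effect(self):
        rng = np.random.default_rng(1)
        base = 10.0 + 0.1 * rng.standard_normal((6, 20))
        resp = base + 10.0
        p_win, _ = px.responsivity_anova(base, resp)
        assert p_win < 1e-10

    def test_forced_interaction(self):
        rng = np.random.default_rng(2)
        base = 10.0 + 0.2 * rng.standard_normal((8, 12))
        bump = np.linspace(0.0, 15.0, 12)
        resp = base + bump + 0.2 * rng.standard_normal((8, 12))
        _, p_int = px.responsivity_anova(base, resp)
        assert p_int < 1e-6

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            px.responsivity_anova(np.zeros((1, 5)), np.zeros((1, 5)))
        with pytest.raises(ValueError):
            px.responsivity_anova(np.zeros((5, 1)), np.zeros((5, 1)))


class TestFanoFactor:
    def test_poisson_slope_near_one(self):
        """Simulation oracle: for Poisson counts, trial variance equals the
        mean, so the regression slope is ~1."""
        rng = np.random.default_rng(3)
        means = np.linspace(1.0, 20.0, 20)
        counts = rng.poisson(means, (5000, 20))
        slope = px.fano_factor(counts / 0.2, window_s=0.2)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_scaled_poisson_slope_near_two(self):
        """Counts = 2 x Poisson(mu): variance 4 mu against mean 2 mu gives
        an OLS slope of ~2 (verified by the same simulation oracle)."""
        rng = np.random.default_rng(4)
        means = np.linspace(1.0, 20.0, 20)
        counts = 2 * rng.poisson(means, (5000, 20))
        slope = px.fano_factor(counts / 0.2, window_s=0.2)
        assert slope == pytest.approx(2.0, abs=0.15)

    def test_deterministic_counts_slope_zero(self):
        counts = np.tile(np.arange(1.0, 11.0), (6, 1))
        assert px.fano_factor(counts / 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_slope(self):
        with pytest.raises(ValueError):
            px.fano_factor(np.ones((5, 4)))


class TestSelectivity:
    def test_forced_effect(self):
        rng = np.random.default_rng(5)
        rates = rng.poisson(5.0, (8, 30)).astype(float)
        rates[:, 15:] = rng.poisson(50.0, (8, 15))
        assert px.selectivity_test(rates) < 1e-6

    def test_single_trial_is_insufficient(self):
        with pytest.raises(ValueError):
            px.selectivity_test(np.ones((1, 10)))


class TestReliability:
    def test_duplicate_trials_give_unity(self):
        rng = np.random.default_rng(6)
        row = rng.gamma(3.0, 4.0, 50)
        rates = np.tile(row, (6, 1))
        assert px.split_half_reliability(rates, n_splits=10, seed=0) == pytest.approx(1.0)

    def test_spearman_brown_closed_form(self):
        assert spearman_brown(0.5) == pytest.approx(2 / 3)
        assert spearman_brown(1.0) == 1.0
        assert spearman_brown(0.0) == 0.0

    def test_noise_only_units_near_zero(self):
        from posexis.unit_selection import split_half_reliability_matrix

        rng = np.random.default_rng(7)
        rates = rng.poisson(10.0, (100, 10, 50)).astype(float)
        rel = split_half_reliability_matrix(
            rates, n_splits=20, rng=np.random.default_rng(8)
        )
        assert abs(np.median(rel)) < 0.1

    def test_single_trial_is_insufficient(self):
        with pytest.raises(ValueError):
            px.split_half_reliability(np.ones((1, 10)))


class TestBsi:
    def test_twofold_preference(self):
        cat = {
            "labels": np.array(["body"] * 20 + ["face"] * 20 + ["object"] * 20),
            "response_rates": np.tile(
                np.r_[np.full(20, 7.0), np.full(40, 6.0)], (5, 1)
            ),
            "baseline_rates": np.full((5, 60), 5.0),
        }
        assert px.compute_bsi(cat) == pytest.approx(1 / 3)

    def test_zero_denominator(self):
        cat = {
            "labels": np.array(["body"] * 20 + ["face"] * 40),
            "response_rates": np.full((5, 60), 5.0),
            "baseline_rates": np.full((5, 60), 5.0),
        }
        with pytest.raises(ZeroDivisionError):
            px.compute_bsi(cat)


def _planted_population(seed=11):
    """30 strongly tuned, 10 unresponsive, 10 stimulus-independent units."""
    rng = np.random.default_rng(seed)
    n_stim, n_trials = 60, 6
    good_cat = px.simulate_category_responses(20.0, 2.0, seed=seed)
    units = []
    for i in range(30):  # strong: tuned, reliable, body-selective
        tuning = np.maximum(10.0 + 15.0 * rng.standard_normal(n_stim), 0.0)
        units.append(UnitRecording(
            unit_id=f"strong{i}",
            response_rates=rng.poisson(tuning * 0.2, (n_trials, n_stim)) / 0.2,
            baseline_rates=rng.poisson(1.0 * 0.1, (n_trials, n_stim)) / 0.1,
            category_rates=good_cat,
        ))
    for i in range(10):  # unresponsive: response == baseline statistics
        units.append(UnitRecording(
            unit_id=f"flat{i}",
            response_rates=rng.poisson(2.0 * 0.2, (n_trials, n_stim)) / 0.2,
            baseline_rates=rng.poisson(2.0 * 0.1, (n_trials, n_stim)) / 0.1,
            category_rates=good_cat,
        ))
    for i in range(10):  # responsive but untuned and unreliable
        units.append(UnitRecording(
            unit_id=f"noise{i}",
            response_rates=rng.poisson(12.0 * 0.2, (n_trials, n_stim)) / 0.2,
            baseline_rates=rng.poisson(2.0 * 0.1, (n_trials, n_stim)) / 0.1,
            category_rates=good_cat,
        ))
    return units


class TestSelectUnits:
    def test_planted_population_recovered(self):
        units = _planted_population()
        reports = px.select_units(units, seed=0)
        passed = {r.unit_id for r in reports if r.passed}
        assert passed == {f"strong{i}" for i in range(30)}

    def test_permissive_thresholds_pass_everything(self):
        units = _planted_population()[:8]
        th = SelectionThresholds(
            responsivity_alpha=1.1, fano_max=np.inf, min_net_rate=-np.inf,
            selectivity_alpha=1.1, min_reliability=-2.0, min_bsi=-2.0,
            bsi_alpha=1.1, n_reliability_splits=20,
        )
        assert all(r.passed for r in px.select_units(units, th, seed=0))

    def test_impossible_reliability_threshold(self):
        units = _planted_population()[:8]
        th = SelectionThresholds(min_reliability=1.01, n_reliability_splits=20)
        assert not any(r.passed for r in px.select_units(units, th, seed=0))

    @pytest.mark.parametrize(
        "field,tight",
        [("responsivity_alpha", 0.001), ("fano_max", 1.0),
         ("min_net_rate", 20.0), ("selectivity_alpha", 0.001),
         ("min_reliability", 0.9), ("min_bsi", 0.9)],
    )
    def test_tightening_thresholds_is_monotone(self, field, tight):
        units = _planted_population()[::4]
        th = SelectionThresholds(n_reliability_splits=20)
        baseline = sum(r.passed for r in px.select_units(units, th, seed=0))
        setattr(th, field, tight)
        tightened = sum(r.passed for r in px.select_units(units, th, seed=0))
        assert tightened <= baseline
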