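"""FGM/BOM indices, zone labeling, bootstrap nulls, time courses."""

import numpy as np
import pandas as pd
import pytest

from figground.modulation import (ModulationResult, ZoneSpec,
                                  bootstrap_significance, compute_bom,
                                  compute_fgm, compute_zone_timecourses,
                                  count_significant_conditions,
                                  label_trials_by_zone, modulation_for_cell,
                                  zone_trial_counts)
from figground.rf_mapping import RFFit


class TestZoneLabeling:
    def test_results_convention_trial_counts(self, canonical_session, grid):
        """Central 2x2 figure zone, outer-column background, column-4/12
        borders give 40/160/80/80 trials per condition-variant."""
        labels = label_trials_by_zone(canonical_session.trials, grid)
        counts = zone_trial_counts(labels, canonical_session.trials)
        for (cond, var) in {("Cross", 1), ("Iso", 2), ("Nat", 1)}:
            sub = counts[(counts.condition == cond) & (counts.variant == var)]
            by_zone = dict(zip(sub.zone, sub.n_trials))
            assert by_zone["figure"] == 40
            assert by_zone["background"] == 160
            assert by_zone["left_border"] == 80
            assert by_zone["right_border"] == 80

    def test_results_zone_positions(self, grid):
        trials = pd.DataFrame({
            "condition": "Cross", "variant": 1,
            "az_bin": [8, 9, 1, 16, 4, 12, 6],
            "el_bin": [4, 5, 3, 3, 2, 7, 6],
            "onset_s": 0.0, "motion_phase": 0.0, "trial": range(7)})
        labels = label_trials_by_zone(trials, grid).tolist()
        assert labels == ["figure", "figure", "background", "background",
                          "left_border", "right_border", "other"]

    def test_methods_convention_centers_on_rf(self, grid):
        rf = RFFit(center=(3.0, 0.0), widths=(1.5, 1.5), amplitude=1.0,
                   offset=0.0, gof=0.9)
        trials = pd.DataFrame({
            "condition": "Cross", "variant": 1,
            "az_bin": list(range(1, 17)), "el_bin": 4,
            "onset_s": 0.0, "motion_phase": 0.0, "trial": range(16)})
        labels = label_trials_by_zone(trials, grid,
                                      ZoneSpec(convention="methods"),
                                      rf_fit=rf)
        # RF at +3 deg azimuth sits between bins 9 and 10
        assert labels[labels == "figure"].index.tolist() == [8, 9]
        # distant columns are background under the 1.5-RF-width rule
        assert (labels.iloc[:3] == "background").all()

    def test_methods_requires_rf(self, grid, canonical_session):
        with pytest.raises(ValueError, match="RF fit"):
            label_trials_by_zone(canonical_session.trials, grid,
                                 ZoneSpec(convention="methods"))


class TestIndices:
    @pytest.mark.parametrize("a, b, expected", [
        (1.0, 0.0, 1.0),
        (2.0, 1.0, pytest.approx(1 / 3)),
        (3.7, 3.7, 0.0),
    ])
    def test_fgm_worked_examples(self, a, b, expected):
        assert compute_fgm(a, b) == expected

    def test_antisymmetry(self):
        assert compute_bom(2.0, 5.0) == -compute_bom(5.0, 2.0)

    def test_bounds(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 10, 2)
            if a + b > 0:
                assert -1.0 <= compute_fgm(a, b) <= 1.0

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            compute_fgm(0.0, 0.0)
        with pytest.raises(ValueError):
            compute_bom(-1.0, 2.0)


class TestBootstrap:
    def test_identical_zone_responses_not_significant(self):
        resp = np.ones(200)
        labels = np.array(["figure"] * 40 + ["background"] * 160)
        value, p = bootstrap_significance(resp, labels, "figure",
                                          "background", n_shuffles=200,
                                          seed=0)
        assert value == 0.0
        assert p > 0.9

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(1)
        resp = np.concatenate([rng.normal(4, 0.5, 40),
                               rng.normal(1, 0.5, 160)]).clip(0)
        labels = np.array(["figure"] * 40 + ["background"] * 160)
        value, p = bootstrap_significance(resp, labels, "figure",
                                          "background", n_shuffles=500,
                                          seed=2)
        assert value > 0.5
        assert p < 0.01

    def test_needs_two_trials_per_zone(self):
        with pytest.raises(ValueError):
            bootstrap_significance(np.ones(3), np.array(["figure", "figure",
                                                         "background"]),
                                   "figure", "background")

    def test_null_pvalues_are_calibrated(self):
        """Exchangeable responses produce ~5% rejections at alpha=0.05."""
        rng = np.random.default_rng(3)
        labels = np.array(["figure"] * 40 + ["background"] * 160)
        rejections = 0
        n_cells = 200
        for i in range(n_cells):
            resp = rng.gamma(2.0, 1.0, 200)
            _, p = bootstrap_significance(resp, labels, "figure",
                                          "background", n_shuffles=200,
                                          seed=1000 + i)
            rejections += p < 0.05
        rate = rejections / n_cells
        assert 0.05 - 0.04 <= rate <= 0.05 + 0.04

    def test_modulation_for_cell_restricts_condition(self, canonical_session,
                                                     grid):
        labels = label_trials_by_zone(canonical_session.trials, grid)
        trials = canonical_session.trials
        resp = np.where(labels == "figure", 2.0, 1.0)
        res = modulation_for_cell(resp, labels, trials, "FGM",
                                  condition="Cross", n_shuffles=100, seed=0)
        assert isinstance(res, ModulationResult)
        assert res.index_value == pytest.approx(1 / 3)
        assert res.n_a == 80 and res.n_b == 320  # both variants pooled
        assert "FGM" in res.summary()


class TestEffectRecovery:
    def test_planted_fgm_recovered_with_small_bias(self):
        """A planted figure-ground effect is estimated with bias < 0.02 at
        the canonical 40/160 trial counts under mean-scaled noise of factor
        2, averaged over 200 simulated cells."""
        rng = np.random.default_rng(8)
        r_fig, r_back = 10.0, 5.0
        true_fgm = compute_fgm(r_fig, r_back)
        popmean = (40 * r_fig + 160 * r_back) / 200.0
        sd = np.sqrt(2.0 * popmean)
        estimates = []
        for _ in range(200):
            fig = np.clip(rng.normal(r_fig, sd, 40), 0, None)
            back = np.clip(rng.normal(r_back, sd, 160), 0, None)
            estimates.append(compute_fgm(fig.mean(), back.mean()))
        assert abs(np.mean(estimates) - true_fgm) < 0.02


class TestSignificanceCounts:
    def test_histogram_and_chance_curve(self):
        p = np.array([[0.01] * 6, [0.5] * 6, [0.01, 0.2, 0.2, 0.2, 0.2, 0.2]])
        counts, hist, chance = count_significant_conditions(p, alpha=0.05)
        assert counts.tolist() == [6, 0, 1]
        assert hist[6] == pytest.approx(1 / 3)
        assert hist[0] == pytest.approx(1 / 3)
        assert chance.sum() == pytest.approx(1.0)
        assert chance[0] == pytest.approx(0.95 ** 6)

    def test_null_counts_match_binomial(self):
        """Independent uniform p-values land on the Binomial(6, alpha) mass
        function within multinomial error."""
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, (3000, 6))
        counts, hist, chance = count_significant_conditions(p, alpha=0.05)
        se = np.sqrt(chance * (1 - chance) / 3000)
        assert np.all(np.abs(hist - chance) < 4 * se + 1e-3)


class TestTimecourses:
    def _labels(self, n_fig=30, n_back=30):
        return pd.Series(["figure"] * n_fig + ["background"] * n_back)

    def test_planted_figure_cell_flags_all_bins(self):
        labels = self._labels()
        x = np.concatenate([np.ones((30, 10)), np.zeros((30, 10))])
        rng = np.random.default_rng(5)
        x = x + 0.01 * rng.standard_normal(x.shape)
        out = compute_zone_timecourses(x, labels)
        assert out["significant"].all()
        assert out["figure"]["mean"].shape == (10,)

    def test_null_flag_rate_near_alpha(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((200, 400))
        out = compute_zone_timecourses(x, self._labels(100, 100), alpha=0.01)
        rate = out["significant"].mean()
        assert rate < 0.03

    def test_flat_zero_traces_do_not_fail(self):
        x = np.zeros((60, 5))
        out = compute_zone_timecourses(x, self._labels())
        assert not out["significant"].any()
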