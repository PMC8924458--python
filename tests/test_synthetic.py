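import numpy as np
import pandas as pd
import pytest

from intentgap.scoring import construct_scores
from intentgap.stats import pearson_corr
from intentgap.survey_io import SCORE_NAMES, filter_complete, write_cohort
from intentgap.synthetic import (
    GeneratorConfig,
    complete_correlation_matrix,
    default_calibration,
    generate_cohort,
    generate_scores,
)


class TestDefaultCalibration:
    def test_self_report_targets(self, default_config):
        assert default_config.target_means["I_H"] == 1.38
        assert default_config.target_sds["I_H"] == 0.69
        assert default_config.target_means["B_S"] == -0.37

    def test_intention_behavior_correlation_target(self, default_config):
        assert default_config.target_correlations[("B_H", "I_H")] == 0.64

    def test_dk_and_cohort_sizes(self, default_config):
        assert default_config.dk_count_behavior == 6
        assert default_config.n_participants == 144
        assert default_config.n_starters == 176

    def test_composite_targets_are_induced(self, default_config):
        # construct-level targets reproduce the composite moments algebraically
        w = np.array([1.4, 1.0, 0.5])
        mus = np.array([default_config.target_means[c] for c in ("A_H", "SN_H", "PBC_H")])
        assert w @ mus == pytest.approx(2.33, abs=1e-9)
        regs = ("R_Int_H", "R_Id_H", "R_Intro_H", "R_Ext_H")
        v = np.array([2.0, 1.0, -1.0, -2.0])
        mur = np.array([default_config.target_means[r] for r in regs])
        assert v @ mur == pytest.approx(2.12, abs=1e-9)

    def test_validation_catches_bad_targets(self, default_config):
        bad = default_calibration()
        bad.target_sds["I_H"] = -1.0
        with pytest.raises(ValueError, match="SD"):
            bad.validate()


class TestCompleteCorrelationMatrix:
    NAMES = ["x", "y", "z"]

    def test_fully_specified_identity(self):
        out = complete_correlation_matrix({}, self.NAMES)
        np.testing.assert_array_equal(out.to_numpy(), np.eye(3))

    def test_partial_entry_preserved_and_pd(self):
        out = complete_correlation_matrix({("x", "y"): 0.5}, self.NAMES)
        assert out.at["x", "y"] == pytest.approx(0.5, abs=1e-9)
        eigs = np.linalg.eigvalsh(out.to_numpy())
        assert eigs.min() > 0

    def test_contradictory_specification_errors(self):
        partial = {("x", "y"): 0.99, ("y", "z"): 0.99, ("x", "z"): -0.99}
        with pytest.raises(ValueError, match="deviation"):
            complete_correlation_matrix(partial, self.NAMES)

    def test_inconsistent_duplicate_errors(self):
        with pytest.raises(ValueError, match="conflicting"):
            complete_correlation_matrix({("x", "y"): 0.5, ("y", "x"): 0.4}, self.NAMES)

    def test_repair_uses_unspecified_entries(self):
        # indefinite when w~z stays 0, but a completion exists: check that the
        # specified entries survive while w~z moves away from 0
        partial = {("x", "y"): 0.9, ("y", "z"): 0.9, ("x", "z"): 0.9,
                   ("x", "w"): 0.8, ("y", "w"): 0.8}
        out = complete_correlation_matrix(partial, ["x", "y", "z", "w"])
        for (a, b), r in partial.items():
            assert out.at[a, b] == pytest.approx(r, abs=0.02)
        assert np.linalg.eigvalsh(out.to_numpy()).min() >= -1e-10


class TestGenerateScores:
    def test_seed_determinism(self, default_config):
        a = generate_scores(default_config, seed=5)
        b = generate_scores(default_config, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = generate_scores(default_config, seed=6)
        assert not a.equals(c)

    def test_large_sample_mean_recovery(self):
        cfg = default_calibration(
            n_participants=100_000, n_starters=100_000,
            dk_count_behavior=0, calibrate_discretization=False,
        )
        cfg.target_means = {k: 0.0 for k in SCORE_NAMES}
        cfg.target_sds = {k: 0.5 for k in SCORE_NAMES}
        table = generate_scores(cfg, seed=1)
        assert abs(table["I_H"].mean()) < 0.01

    def test_truncation_attenuates_boundary_sd(self):
        cfg = default_calibration(calibrate_discretization=False,
                                  n_participants=50_000, n_starters=50_000,
                                  dk_count_behavior=0)
        table = generate_scores(cfg, seed=2)
        # B_S targets (-0.37, 1.03): truncation at the scale ends shrinks SD
        assert table["B_S"].std(ddof=1) < 1.03
        assert table["B_S"].min() >= -2 and table["B_S"].max() <= 2


class TestGenerateCohort:
    def test_byte_identical_for_same_seed(self, default_config, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(generate_cohort(default_config, 3), p1)
        write_cohort(generate_cohort(default_config, 3), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_completer_count_and_dropout_shape(self, cohort144, default_config):
        complete = filter_complete(cohort144)
        assert complete.n == default_config.n_participants
        dropouts = cohort144.values.iloc[default_config.n_participants:]
        answered = dropouts.notna()
        assert set(answered.columns[answered.any()]) == set(default_config.dropout_items)

    def test_dk_placement(self, cohort144, default_config):
        dk = cohort144.dont_know
        assert int(dk.to_numpy().sum()) == default_config.dk_count_behavior
        assert dk.drop(columns=default_config.dk_item).to_numpy().sum() == 0
        # DK responders are completers
        assert cohort144.complete[dk[default_config.dk_item]].all()

    def test_zero_noise_single_item_items_equal_latents(self):
        cfg = default_calibration(
            items_per_construct=1, item_noise_sd=0.0,
            calibrate_discretization=False, n_participants=50, n_starters=50,
            dk_count_behavior=0,
        )
        coh = generate_cohort(cfg, 9)
        latent = generate_scores(cfg, 9).iloc[:50]
        # items are the rounded truncated latents, bit for bit
        expected = np.clip(np.rint(latent["A_H"].to_numpy()), -2, 2)
        np.testing.assert_array_equal(coh.values["A_H_1"].to_numpy(), expected)

    def test_replicate_averaged_construct_means_near_targets(self, default_config):
        sums = {k: 0.0 for k in SCORE_NAMES}
        reps = 25
        for i in range(reps):
            scores = construct_scores(filter_complete(generate_cohort(default_config, 300 + i)))
            for k in sums:
                sums[k] += scores[k].mean()
        for k, total in sums.items():
            assert total / reps == pytest.approx(
                default_config.target_means[k], abs=0.15
            ), k

    def test_realized_correlation_monotone_in_target(self):
        realized = []
        for target in (0.2, 0.5, 0.8):
            cfg = default_calibration(n_participants=20_000, n_starters=20_000,
                                      dk_count_behavior=0)
            cfg.target_correlations[("B_H", "I_H")] = target
            scores = construct_scores(generate_cohort(cfg, 11))
            realized.append(pearson_corr(scores["I_H"], scores["B_H"]).statistic)
        assert realized[0] < realized[1] < realized[2]


class TestConfigValidation:
    def test_starters_fewer_than_completers(self):
        with pytest.raises(ValueError, match="n_starters"):
            default_calibration(n_starters=100).validate()

    def test_correlation_out_of_range(self):
        cfg = default_calibration()
        cfg.target_correlations[("B_H", "I_H")] = 1.5
        with pytest.raises(ValueError, match="outside"):
            cfg.validate()

    def test_negative_noise(self):
        with pytest.raises(ValueError, match="noise"):
            default_calibration(item_noise_sd=-0.1).validate()
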