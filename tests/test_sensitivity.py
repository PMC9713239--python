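"""Delta moment-independent measure, QMC sampling, rank penalties."""

import inspect

import numpy as np
import pytest

from kneeplan import knee_core as kc, planning as pl, sensitivity as sa


class TestQmcPoseSamples:
    def test_default_sample_count(self):
        assert inspect.signature(sa.qmc_pose_samples).parameters["n"].default == 256

    def test_first_point_is_median(self):
        samples = sa.qmc_pose_samples(pl.PRESETS["pr90"], 64, seed=0)
        assert np.all(samples[0] == 0.0)

    def test_sample_sd_tracks_preset(self):
        samples = sa.qmc_pose_samples(pl.PRESETS["pr90"], 256, seed=0)
        sd = samples.std(axis=0)
        assert np.all(np.abs(sd - pl.PRESETS["pr90"].sigma)
                      / pl.PRESETS["pr90"].sigma < 0.10)

    def test_incomplete_preset_rejected(self):
        with pytest.raises(ValueError):
            sa.qmc_pose_samples(pl.PRESETS["conventional"], 16, seed=0)


class TestDeltaMeasure:
    def test_independent_input_scores_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (2000, 2))
        y = rng.normal(0, 1, 2000)
        res = sa.delta_measure(x, y, seed=1)
        assert np.all(res.delta < 0.05)

    def test_driving_input_dominates_noise_input(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (5000, 2))
        y = x[:, 0].copy()
        res = sa.delta_measure(x, y, seed=1)
        assert res.delta[0] > res.delta[1]
        assert res.delta[1] < 0.05
        assert res.delta[0] > 0.5

    def test_exchangeable_inputs_score_equally(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (5000, 2))
        y = x.sum(axis=1)
        res = sa.delta_measure(x, y, seed=1)
        assert abs(res.delta[0] - res.delta[1]) < 0.03

    def test_bounded_and_rescaling_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (5000, 3))
        y = x[:, 0] + 0.5 * x[:, 1]
        r1 = sa.delta_measure(x, y, seed=1)
        r2 = sa.delta_measure(x, 3.0 * y - 7.0, seed=1)
        assert np.all((r1.delta >= 0) & (r1.delta <= 1))
        assert np.max(np.abs(r1.delta - r2.delta)) < 0.02

    def test_constant_output_warns_and_zeros(self):
        x = np.random.default_rng(0).uniform(0, 1, (200, 2))
        with pytest.warns(UserWarning, match="constant output"):
            res = sa.delta_measure(x, np.ones(200))
        assert np.all(res.delta == 0.0)

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError):
            sa.delta_measure(np.zeros((50, 2)), np.zeros(50))

    def test_classification_sizes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (1000, 12))
        y = x @ np.linspace(1, 0.1, 12)
        res = sa.delta_measure(x, y, seed=1, names=tuple(f"p{i}" for i in range(12)))
        cls = res.classification()
        assert len(cls["most"]) == 3
        assert len(cls["mid"]) == 3
        assert len(cls["least"]) == 4


class TestConvergencePenalty:
    def test_identical_sets_any_order(self):
        truth = [f"p{i}" for i in range(10)]
        shuffled = truth[::-1]
        assert sa.convergence_penalty(shuffled, truth).penalty == 0.0

    def test_missing_most_critical(self):
        truth = [f"p{i}" for i in range(10)]
        evaluated = ["x"] + truth[1:]
        assert sa.convergence_penalty(evaluated, truth).penalty == 10.0

    def test_missing_top_two(self):
        truth = [f"p{i}" for i in range(10)]
        evaluated = ["x", "y"] + truth[2:]
        assert sa.convergence_penalty(evaluated, truth).penalty == 15.0

    def test_duplicates_rejected(self):
        truth = [f"p{i}" for i in range(10)]
        with pytest.raises(ValueError):
            sa.convergence_penalty(["p0"] * 10, truth)


class TestConvergenceCurve:
    def _linear_data(self, n=600, d=12, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (n, d))
        # distinct effect sizes so the full-sample ranking is well defined
        coeff = np.geomspace(3.0, 0.15, d)
        y = x @ coeff + 0.1 * rng.normal(0, 1, n)
        return x, y

    def test_default_repeat_count(self):
        default = inspect.signature(sa.sa_convergence_curve).parameters["n_repeats"]
        assert default.default == 50

    def test_full_subset_has_zero_penalty(self):
        x, y = self._linear_data()
        curve = sa.sa_convergence_curve(x, y, [600], n_repeats=3, seed=1)
        assert curve["mean_penalty"][0] == 0.0

    def test_penalty_nonincreasing_with_sample_size(self):
        x, y = self._linear_data()
        curve = sa.sa_convergence_curve(x, y, [150, 300, 600],
                                        n_repeats=8, seed=1)
        m = curve["mean_penalty"]
        s = curve["std_penalty"]
        assert m[1] <= m[0] + max(s[0], 1e-9)
        assert m[2] <= m[1] + max(s[1], 1e-9)
        assert m[2] == 0.0

    def test_oversized_subset_rejected(self):
        x, y = self._linear_data(n=200)
        with pytest.raises(ValueError):
            sa.sa_convergence_curve(x, y, [500], n_repeats=2)


class TestCollectSamples:
    def test_contract_and_determinism(self, subject, family_d, postka_surrogate):
        geometry, _ = subject
        model, _ = postka_surrogate

        def factory(row):
            return pl.SurrogateKneeModel(model, geometry, row[None, :])

        ga = pl.GAConfig(generations=2, offspring=8, seed=1)
        out = sa.collect_sa_samples(family_d, factory, pl.PRESETS["pr90"],
                                    n_sets=6, n_qmc=16, ga=ga, seed=3)
        assert len(out) == 6
        for s in out:
            assert np.isfinite(s.gsp) and 0 <= s.gsp <= 1
            assert np.all(np.isfinite(s.pose))
        out2 = sa.collect_sa_samples(family_d, factory, pl.PRESETS["pr90"],
                                     n_sets=6, n_qmc=16, ga=ga, seed=3)
        assert np.array_equal(np.stack([s.pose for s in out]),
                              np.stack([s.pose for s in out2]))

    def test_variance_dominant_parameter_ranks_top3(self, subject,
                                                    postka_surrogate):
        """A bundle whose reference strain carries 10x the variance of every
        other input should rank among the top 3 for success probability."""
        geometry, props = subject
        model, _ = postka_surrogate
        rng = np.random.default_rng(8)
        n = 400
        fam = np.tile(props, (n, 1))
        noise_sd = np.zeros(50)
        for name in kc.PARAM_NAMES:
            i = kc.LAYOUT.index(name)
            if name.endswith(".eps_r"):
                noise_sd[i] = 0.004
            elif name.endswith(".k"):
                noise_sd[i] = 100.0
            else:
                noise_sd[i] = 0.2
        target = kc.LAYOUT.index("supMCL.eps_r")
        noise_sd[target] = 0.004 * np.sqrt(10.0)
        fam = fam + rng.normal(0, 1, (n, 50)) * noise_sd
        fam = np.clip(fam, kc.LAYOUT.lower, kc.LAYOUT.upper)

        def factory(row):
            return pl.SurrogateKneeModel(model, geometry, row[None, :])

        out = sa.collect_sa_samples(fam, factory, pl.PRESETS["pr90"],
                                    n_sets=n, n_qmc=32, seed=4, optimize=False)
        inputs = np.stack([s.props for s in out])
        gsp = np.array([s.gsp for s in out])
        res = sa.delta_measure(inputs, gsp, seed=2, names=kc.PARAM_NAMES)
        assert "supMCL.eps_r" in res.top(3), res.top(10)
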