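"""Precision presets, Monte Carlo machinery, Eq.-style objective, GA."""

import numpy as np
import pytest

from kneeplan import knee_core as kc, planning as pl
from kneeplan.knee_core import FlexionSchedule, ImplantPose


class _FixedStrainModel:
    """Test stub returning a prescribed strain table."""

    def __init__(self, table):
        self.table = np.asarray(table, float)

    def strain_table(self, poses, rows, schedule):
        n = poses.shape[0]
        return np.broadcast_to(self.table, (n,) + self.table.shape).copy()


class TestPresets:
    def test_pr90_femoral_varus_valgus(self):
        assert pl.PRESETS["pr90"].sigma[4] == pytest.approx(0.33)

    def test_ras_tibial_slope(self):
        assert pl.PRESETS["ras"].sigma[9] == pytest.approx(1.6)

    def test_conventional_tibial_internal_external(self):
        assert pl.PRESETS["conventional"].sigma[11] == pytest.approx(9.0)

    def test_incomplete_presets_flag_na(self):
        assert not pl.PRESETS["conventional"].complete
        assert not pl.PRESETS["ras_mako"].complete
        assert pl.PRESETS["ras"].complete
        assert pl.PRESETS["pr90"].complete

    def test_draw_rejects_incomplete_preset(self):
        with pytest.raises(ValueError, match="complete preset"):
            pl.draw_base_samples(pl.PRESETS["psg"], 16, seed=0)


class TestBaseSamples:
    def test_sample_sd_matches_preset(self):
        samples = pl.draw_base_samples(pl.PRESETS["pr90"], 4096, seed=3)
        sd = samples.perturbations.std(axis=0)
        assert abs(sd[4] - 0.33) / 0.33 < 0.05       # femoral V/V column
        assert np.all(np.abs(sd - pl.PRESETS["pr90"].sigma)
                      / pl.PRESETS["pr90"].sigma < 0.08)

    def test_zero_sigma_yields_zero_samples(self):
        preset = pl.PrecisionPreset("exact", np.zeros(12))
        samples = pl.draw_base_samples(preset, 64, seed=0)
        assert np.all(samples.perturbations == 0.0)

    def test_scaling_preset_scales_same_draw(self):
        a = pl.draw_base_samples(pl.PRESETS["pr90"], 128, seed=5)
        b = pl.draw_base_samples(pl.PRESETS["pr90"].scaled(2.0), 128, seed=5)
        assert np.allclose(b.perturbations, 2.0 * a.perturbations)
        assert np.array_equal(a.property_rows, b.property_rows)

    def test_transform_identity_and_shift(self):
        base = pl.draw_base_samples(pl.PRESETS["ras"], 32, seed=1)
        frozen = base.perturbations.copy()
        assert np.array_equal(pl.transform_samples(base, np.zeros(12)), frozen)
        x = np.zeros(12)
        x[1] = 1.0
        shifted = pl.transform_samples(base, x)
        assert np.allclose(shifted[:, 1] - frozen[:, 1], 1.0)
        assert np.array_equal(base.perturbations, frozen)
        assert np.allclose(shifted.mean(axis=0) - frozen.mean(axis=0), x,
                           atol=1e-12)


class TestObjective:
    def _samples(self, n):
        return pl.MCSampleSet(perturbations=np.zeros((n, 12)),
                              property_rows=np.zeros(n, dtype=int), seed=0)

    def test_all_in_zone_zero_objective(self):
        model = _FixedStrainModel(np.full((6, 3), 0.02))
        oo = pl.objective(np.zeros(12), self._samples(4), model,
                          FlexionSchedule(np.array([20.0, 70.0, 120.0])))
        assert oo.total == 0.0
        assert oo.u1 == 0.0 and oo.u2 == 0.0

    def test_single_overstrain_penalty(self):
        table = np.full((6, 7), 0.02)
        table[2, 3] = 0.08                    # one ligament, one angle
        oo = pl.objective(np.zeros(12), self._samples(1),
                          _FixedStrainModel(table), FlexionSchedule())
        assert oo.u1 == pytest.approx(4e-4)
        assert oo.total == pytest.approx(4e-3)   # x10 / n_MCS=1

    def test_regularization_only(self):
        model = _FixedStrainModel(np.full((6, 7), 0.02))
        x = np.zeros(12)
        x[0] = 2.0
        oo = pl.objective(x, self._samples(1), model, FlexionSchedule())
        assert oo.total == pytest.approx(0.005 * 4.0)
        assert oo.regularization == pytest.approx(0.02)

    def test_engagement_penalty_uses_group_maxima(self):
        table = np.full((6, 7), 0.02)
        for b in ("LCL", "ALL", "PFL"):
            table[kc.RETAINED_BUNDLES.index(b), :] = -0.01
        oo = pl.objective(np.zeros(12), self._samples(1),
                          _FixedStrainModel(table), FlexionSchedule())
        assert oo.u2 == pytest.approx(7 * 1e-4)

    def test_vectorized_matches_literal_triple_loop(self):
        """The closed-form objective equals a literal transcription."""
        rng = np.random.default_rng(42)
        n_mcs, t = 8, 3
        schedule = FlexionSchedule(np.array([20.0, 70.0, 120.0]))
        strains = rng.uniform(-0.1, 0.1, (n_mcs, 6, t))

        class _PerSample:
            def strain_table(self, poses, rows, schedule):
                return strains

        x = rng.uniform(-2, 2, 12)
        oo = pl.objective(x, self._samples(n_mcs), _PerSample(), schedule)

        med = [kc.RETAINED_BUNDLES.index(b) for b in ("deepMCL", "supMCL")]
        lat = [kc.RETAINED_BUNDLES.index(b) for b in ("LCL", "ALL", "PFL")]
        total = 0.0
        for s in range(n_mcs):
            u1 = 0.0
            for li in range(6):
                for ti in range(t):
                    eps = strains[s, li, ti]
                    if eps > 0.06:
                        u1 += (eps - 0.06) ** 2
            u2 = 0.0
            for ti in range(t):
                lat_max = max(strains[s, li, ti] for li in lat)
                med_max = max(strains[s, li, ti] for li in med)
                if lat_max < 0:
                    u2 += lat_max ** 2
                if med_max < 0:
                    u2 += med_max ** 2
            total += u1 + u2
        expected = 10.0 / n_mcs * total + 0.005 * sum(v ** 2 for v in x)
        assert oo.total == pytest.approx(expected, abs=1e-12)


class TestSuccessProbability:
    def test_all_balanced(self):
        model = _FixedStrainModel(np.full((6, 7), 0.02))
        samples = pl.MCSampleSet(np.zeros((8, 12)), np.zeros(8, int), 0)
        assert pl.success_probability(np.zeros(12), samples, model,
                                      FlexionSchedule()) == 1.0

    def test_hand_constructed_half_balanced(self):
        tables = np.full((4, 6, 7), 0.02)
        tables[1, 0, 3] = 0.08                 # overstrain
        tables[3, 2:5, :] = -0.01              # lateral group slack

        class _PerSample:
            def strain_table(self, poses, rows, schedule):
                return tables

        samples = pl.MCSampleSet(np.zeros((4, 12)), np.zeros(4, int), 0)
        assert pl.success_probability(np.zeros(12), samples, _PerSample(),
                                      FlexionSchedule()) == 0.5


class TestOptimizer:
    def test_paraboloid_recovers_known_optimum(self):
        x_star = np.array([1.5, -2.0, 0.5, 3.0, -1.0, 0.0,
                           2.0, -0.5, 1.0, -3.0, 0.3, -1.2])
        samples = pl.MCSampleSet(np.zeros((1, 12)), np.zeros(1, int), 0)
        res = pl.optimize_plan(
            samples, None,
            pl.GAConfig(generations=120, offspring=64, seed=2),
            FlexionSchedule(),
            objective_fn=lambda pop: np.sum((pop - x_star) ** 2, axis=1))
        assert np.all(np.abs(res.pose.values - x_star) < 0.05)

    def test_never_worse_than_mechanical_alignment(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.5, 2.0, 12)

        def obj(pop):
            return np.sum(a * pop ** 2, axis=1) + 1.0

        samples = pl.MCSampleSet(np.zeros((1, 12)), np.zeros(1, int), 0)
        res = pl.optimize_plan(samples, None,
                               pl.GAConfig(generations=5, offspring=16, seed=9),
                               FlexionSchedule(), objective_fn=obj)
        assert res.trace[-1] <= obj(np.zeros((1, 12)))[0]

    def test_seeded_determinism(self):
        def obj(pop):
            return np.sum(pop ** 2, axis=1) + np.sin(pop).sum(axis=1)

        samples = pl.MCSampleSet(np.zeros((2, 12)), np.zeros(2, int), 0)
        cfg = pl.GAConfig(generations=20, offspring=32, seed=5)
        r1 = pl.optimize_plan(samples, None, cfg, FlexionSchedule(), objective_fn=obj)
        r2 = pl.optimize_plan(samples, None, cfg, FlexionSchedule(), objective_fn=obj)
        assert np.array_equal(r1.pose.values, r2.pose.values)
        assert np.array_equal(r1.trace, r2.trace)

    def test_evaluation_count_identity(self):
        model = _FixedStrainModel(np.full((6, 7), 0.02))
        samples = pl.MCSampleSet(np.zeros((16, 12)), np.zeros(16, int), 0)
        cfg = pl.GAConfig(generations=3, offspring=8, seed=0)
        res = pl.optimize_plan(samples, model, cfg, FlexionSchedule())
        assert res.n_evaluations == pl.evaluations_per_optimization(16, 7, 8, 3)

    def test_gsp_in_unit_interval(self, subject, family_d, postka_surrogate):
        geometry, _ = subject
        model, _ = postka_surrogate
        smodel = pl.SurrogateKneeModel(model, geometry, family_d.props)
        samples = pl.draw_base_samples(pl.PRESETS["ras"], 64, seed=13,
                                       n_family=len(family_d))
        gsp = pl.success_probability(np.zeros(12), samples, smodel,
                                     FlexionSchedule())
        assert 0.0 <= gsp <= 1.0


class TestGspMonotonicity:
    def test_doubling_sigma_never_increases_gsp(self, subject, family_d):
        """Common random numbers: inflating surgical error cannot help."""
        geometry, _ = subject
        model = pl.DirectKneeModel(geometry, family_d.props)
        schedule = FlexionSchedule()
        n = 256
        a = pl.draw_base_samples(pl.PRESETS["pr90"], n, seed=17,
                                 n_family=len(family_d))
        b = pl.draw_base_samples(pl.PRESETS["pr90"].scaled(2.0), n, seed=17,
                                 n_family=len(family_d))
        g1 = pl.success_probability(np.zeros(12), a, model, schedule)
        g2 = pl.success_probability(np.zeros(12), b, model, schedule)
        se = np.sqrt(max(g1 * (1 - g1), 1e-6) / n)
        assert g2 <= g1 + 2 * se
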