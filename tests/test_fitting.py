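"""Ensemble (Tikhonov-NNLS) and mixture-fraction inference."""

import numpy as np
import pytest

import flexsas as fx
from flexsas.fitting import HINGE_ORDER, hinge_angle_stats
from flexsas.synthetic import NoiseSpec, make_ensemble_dataset


def indistinguishable_from(basis, i, noise_rel=0.02):
    """Members whose scale-matched curves differ from member ``i`` by less
    than the data noise (χ²-metric < 1): the mirror-bend degeneracy class.
    Individual weights are only identifiable up to these sets."""
    ref = basis.curves[i]
    sigma = noise_rel * ref
    scale = ref[0] / basis.curves[:, 0]
    d2 = (((scale[:, None] * basis.curves - ref) / sigma) ** 2).mean(axis=1)
    return d2 < 1.0


class TestBuildHingeBasis:
    def test_full_grid_size(self, hinge_basis):
        # 7³ grid members minus the clash-excluded conformers
        assert hinge_basis.n_members + len(hinge_basis.excluded) == 343
        assert len(hinge_basis.excluded) < 10

    def test_member_order_lexicographic(self, hinge_basis):
        idx = np.lexsort(hinge_basis.angles.T[::-1])
        assert np.array_equal(idx, np.arange(hinge_basis.n_members))

    def test_single_zero_member_matches_straight_model(self, toy_dimer,
                                                       saxs_q):
        model, smap = toy_dimer
        basis = fx.build_hinge_basis(model, saxs_q, None, "xray",
                                     angle_grid=(0,), segment_map=smap)
        assert basis.n_members == 1
        straight = fx.debye_curve(model, None, saxs_q)
        assert np.allclose(basis.curves[0], straight.I, rtol=1e-9)

    def test_member_equals_prebent_model_curve(self, toy_dimer, saxs_q,
                                               hinge_basis):
        model, smap = toy_dimer
        target = (60.0, 0.0, 0.0)
        i = int(np.where((hinge_basis.angles == target).all(axis=1))[0][0])
        bent = fx.bend_at_hinge(model, fx.HingeBend("HAMP1", 60.0), smap)
        c = fx.debye_curve(bent, None, saxs_q)
        assert np.allclose(hinge_basis.curves[i], c.I, rtol=1e-9)

    def test_empty_grid_rejected(self, toy_dimer, saxs_q):
        model, smap = toy_dimer
        with pytest.raises(ValueError):
            fx.build_hinge_basis(model, saxs_q, angle_grid=(),
                                 segment_map=smap)


class TestTikhonovNnls:
    def test_single_member_exact_recovery(self, hinge_basis):
        i = 100
        I = hinge_basis.curves[i]
        curve = fx.ScatteringCurve(hinge_basis.q, I,
                                   1e-4 * I.max() * np.ones_like(I))
        sol = fx.tikhonov_nnls(hinge_basis, curve, alpha=0.0)
        assert sol.weights[i] == pytest.approx(1.0, abs=1e-6)
        assert np.delete(sol.weights, i).max() < 1e-6

    def test_three_member_mixture_recovery_by_class(self, toy_dimer, saxs_q):
        # member-level weights are identifiable only on a coarse, well-
        # separated basis (on the full 343-member grid whole weight vectors
        # are exchangeable within noise); aggregate over each truth member's
        # indistinguishability class
        model, smap = toy_dimer
        basis = fx.build_hinge_basis(model, saxs_q, None, "xray",
                                     angle_grid=(-90, 0, 90),
                                     segment_map=smap)
        targets = [(0.0, 0.0, 0.0), (90.0, 0.0, 0.0), (0.0, -90.0, 0.0)]
        idxs = [int(np.where((basis.angles == t).all(axis=1))[0][0])
                for t in targets]
        wts = [0.5, 0.3, 0.2]
        I = sum(w * basis.curves[i] for w, i in zip(wts, idxs))
        s = 0.02 * I
        rng = np.random.default_rng(1)
        curve = fx.ScatteringCurve(basis.q,
                                   I + rng.standard_normal(len(I)) * s, s)
        sol = fx.tikhonov_nnls(basis, curve, alpha=0.0)
        classes = [indistinguishable_from(basis, i) for i in idxs]
        for a in range(3):  # classes must not double-count
            for b in range(a + 1, 3):
                assert not np.any(classes[a] & classes[b])
        for cls, w in zip(classes, wts):
            assert sol.weights[cls].sum() == pytest.approx(w, abs=0.05)

    def test_rms_angle_recovery(self, hinge_basis):
        curve, w_true = make_ensemble_dataset(hinge_basis, 55.0, 2000,
                                              NoiseSpec(seed=3), 7)
        truth = hinge_angle_stats(w_true, hinge_basis)
        sol = fx.tikhonov_nnls(hinge_basis, curve, "auto")
        for h in HINGE_ORDER:
            assert sol.rms_angles[h] == pytest.approx(truth[h], abs=10.0)

    def test_misfit_nondecreasing_in_alpha(self, hinge_basis):
        curve, _ = make_ensemble_dataset(hinge_basis, 55.0, 500,
                                         NoiseSpec(seed=9), 13)
        chis = [fx.tikhonov_nnls(hinge_basis, curve, a).chi2
                for a in (0.0, 1.0, 100.0, 1e4, 1e6)]
        assert all(b >= a * (1 - 1e-9) for a, b in zip(chis, chis[1:]))

    def test_weights_normalized(self, hinge_basis):
        curve, _ = make_ensemble_dataset(hinge_basis, 40.0, 500,
                                         NoiseSpec(seed=2), 5)
        sol = fx.tikhonov_nnls(hinge_basis, curve, "auto")
        assert sol.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(sol.weights >= 0)

    def test_sigma_required(self, hinge_basis):
        curve = fx.ScatteringCurve(hinge_basis.q, hinge_basis.curves[0])
        with pytest.raises(ValueError, match="sigma"):
            fx.tikhonov_nnls(hinge_basis, curve)


class TestHingeAngleStats:
    def test_all_weight_on_straight_member(self, hinge_basis):
        w = np.zeros(hinge_basis.n_members)
        i = int(np.where((hinge_basis.angles == 0).all(axis=1))[0][0])
        w[i] = 1.0
        stats = hinge_angle_stats(w, hinge_basis)
        assert all(v == 0.0 for v in stats.values())

    def test_uniform_grid_arithmetic(self, hinge_basis):
        # uniform weights over the full grid: RMS = √(Σθ²/7) per hinge
        w = np.full(hinge_basis.n_members, 1.0 / hinge_basis.n_members)
        stats = hinge_angle_stats(w, hinge_basis)
        expect = np.sqrt(sum(t ** 2 for t in range(-90, 91, 30)) / 7)
        for h in HINGE_ORDER:  # 2 of 343 members are clash-excluded
            assert stats[h] == pytest.approx(expect, rel=0.02)


class TestMixtureFractions:
    def test_pure_dimer(self, sans_setup):
        cd = sans_setup["dimer_curve"]
        s = 0.01 * cd.I
        exp = fx.ScatteringCurve(cd.q, cd.I, s)
        res = fx.mixture_fractions([cd, sans_setup["trimer_curve"]], exp)
        assert res.fractions[0] == pytest.approx(100.0, abs=0.5)

    def test_known_fraction_recovery(self, sans_setup):
        from flexsas.synthetic import make_mixture_dataset
        curve, _ = make_mixture_dataset(sans_setup["dimer_curve"],
                                        sans_setup["trimer_curve"], 0.36,
                                        NoiseSpec(seed=111), 11)
        res = fx.mixture_fractions([sans_setup["dimer_curve"],
                                    sans_setup["trimer_curve"]], curve)
        assert res.fractions[1] == pytest.approx(36.0, abs=3.0)
        assert res.fractions.sum() == pytest.approx(100.0)
        assert np.all(res.uncertainties >= 0)

    def test_scale_invariance(self, sans_setup):
        from flexsas.synthetic import make_mixture_dataset
        curve, _ = make_mixture_dataset(sans_setup["dimer_curve"],
                                        sans_setup["trimer_curve"], 0.28,
                                        NoiseSpec(seed=5), 3)
        comps = [sans_setup["dimer_curve"], sans_setup["trimer_curve"]]
        r1 = fx.mixture_fractions(comps, curve)
        scaled = fx.ScatteringCurve(curve.q, 17.0 * curve.I,
                                    17.0 * curve.sigma)
        r2 = fx.mixture_fractions(comps, scaled)
        assert np.allclose(r1.fractions, r2.fractions, atol=1e-9)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-9)

    def test_collinear_components_warn(self, sans_setup):
        cd = sans_setup["dimer_curve"]
        s = 0.01 * cd.I
        exp = fx.ScatteringCurve(cd.q, cd.I, s)
        near = fx.ScatteringCurve(cd.q, cd.I * (1 + 1e-12))
        res = fx.mixture_fractions([cd, near], exp)
        assert res.warnings

    def test_recovery_bias_below_2pc(self, sans_setup):
        # average absolute bias over seeds at SANS-like noise
        from flexsas.synthetic import make_mixture_dataset
        comps = [sans_setup["dimer_curve"], sans_setup["trimer_curve"]]
        errs = []
        for seed in range(10):
            curve, _ = make_mixture_dataset(comps[0], comps[1], 0.36,
                                            NoiseSpec(seed=1000 + seed), seed)
            res = fx.mixture_fractions(comps, curve)
            errs.append(res.fractions[1] - 36.0)
        assert abs(np.mean(errs)) < 2.0


class TestCompareTrimerHypotheses:
    def test_tripod_data_ranks_tripod_first(self, sans_setup, toy_dimer):
        from flexsas.synthetic import make_mixture_dataset
        model, _ = toy_dimer
        curve, _ = make_mixture_dataset(sans_setup["dimer_curve"],
                                        sans_setup["trimer_curve"], 0.36,
                                        NoiseSpec(seed=21), 2)
        tm_bound = fx.assemble_c3(model, 18.0, "tm_bound")
        ranked = fx.compare_trimer_models(curve, model,
                                          sans_setup["trimer"], tm_bound,
                                          sans_setup["solvent"], "neutron")
        assert ranked[0][0] == "tripod"
        assert ranked[0][1].chi2 < ranked[1][1].chi2

    def test_tm_bound_data_ranks_tm_bound_first(self, sans_setup, toy_dimer):
        from flexsas.synthetic import component_curves, make_mixture_dataset
        model, _ = toy_dimer
        tm_bound = fx.assemble_c3(model, 18.0, "tm_bound")
        cd, ctb = component_curves(model, tm_bound, sans_setup["solvent"],
                                   sans_setup["q"], "neutron")
        curve, _ = make_mixture_dataset(cd, ctb, 0.36, NoiseSpec(seed=22), 4)
        ranked = fx.compare_trimer_models(curve, model,
                                          sans_setup["trimer"], tm_bound,
                                          sans_setup["solvent"], "neutron")
        assert ranked[0][0] == "tm_bound"

    def test_identical_hypotheses_tie(self, sans_setup, toy_dimer):
        from flexsas.synthetic import make_mixture_dataset
        model, _ = toy_dimer
        curve, _ = make_mixture_dataset(sans_setup["dimer_curve"],
                                        sans_setup["trimer_curve"], 0.3,
                                        NoiseSpec(seed=23), 6)
        ranked = fx.compare_trimer_models(curve, model,
                                          sans_setup["trimer"],
                                          sans_setup["trimer"],
                                          sans_setup["solvent"], "neutron")
        assert ranked[0][1].chi2 == pytest.approx(ranked[1][1].chi2,
                                                  rel=1e-12)
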