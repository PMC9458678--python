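"""Debye forward model, profile averaging and curve fitting."""

import numpy as np
import pytest

from saxsens.formfactors import cromer_mann, scatterers_for
from saxsens.saxs_forward import (
    ScatteringCurve,
    debye_curve,
    fit_to_experiment,
    load_curve,
    save_curve,
    weighted_average_profile,
)

from conftest import make_conformer, random_rotation


def debye_reference(pos, factors, q):
    """Independent O(N²) double-sum evaluation of the Debye equation."""
    n = len(pos)
    out = np.zeros_like(q)
    for iq, qv in enumerate(q):
        total = 0.0
        for i in range(n):
            for j in range(n):
                rij = np.linalg.norm(pos[i] - pos[j])
                x = qv * rij
                sinc = 1.0 if x == 0.0 else np.sin(x) / x
                total += factors[i, iq] * factors[j, iq] * sinc
        out[iq] = total
    return out


class TestDebyeCurve:
    def test_single_scatterer_unit(self):
        conf = make_conformer([[1.0, 2.0, 3.0]])
        q = np.linspace(0.0, 0.5, 11)
        curve = debye_curve(conf, q)
        np.testing.assert_allclose(curve.I, 1.0)

    def test_two_scatterers_analytic(self):
        conf = make_conformer([[0, 0, 0], [10.0, 0, 0]])
        q = np.linspace(0.0, 0.5, 21)
        curve = debye_curve(conf, q)
        with np.errstate(invalid="ignore"):
            expected = 2.0 * (1.0 + np.sinc(10.0 * q / np.pi))
        assert curve.I[0] == pytest.approx(4.0)
        np.testing.assert_allclose(curve.I, expected, rtol=1e-12)

    @pytest.mark.parametrize("model", ["unit", "atomic"])
    def test_matches_brute_force_oracle(self, rng, model):
        """50-bead conformer vs direct double sum, relative 1e-10."""
        coords = rng.normal(scale=10.0, size=(50, 3))
        elements = rng.choice(["C", "N", "O", "S"], size=50)
        conf = make_conformer(coords, elements=list(elements))
        q = np.linspace(0.0, 0.4, 7)
        pos, fac = scatterers_for(conf, q, model)
        expected = debye_reference(pos, fac, q)
        got = debye_curve(conf, q, model).I
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_rotation_translation_invariance(self, random_conformer, rng):
        q = np.linspace(0.0, 0.4, 15)
        base = debye_curve(random_conformer, q).I
        moved = random_conformer.transformed(random_rotation(rng),
                                             rng.normal(scale=30.0, size=3))
        np.testing.assert_allclose(debye_curve(moved, q).I, base, rtol=1e-9)

    def test_intensity_positive_and_i0(self, random_conformer):
        q = np.linspace(0.0, 0.5, 30)
        curve = debye_curve(random_conformer, q)
        assert np.all(curve.I > 0)
        assert curve.I[0] == pytest.approx(50.0 ** 2)

    def test_negative_q_rejected(self, random_conformer):
        with pytest.raises(ValueError):
            debye_curve(random_conformer, np.array([-0.1, 0.1]))

    def test_residue_beads_reduce_scatterers(self):
        conf = make_conformer([[0, 0, 0], [1, 0, 0], [5, 0, 0]],
                              resids=[1, 1, 2], resnames=["GLY", "GLY", "ALA"])
        pos, fac = scatterers_for(conf, np.array([0.0]), "residue")
        assert pos.shape == (2, 3)
        assert fac[0, 0] == 30.0 and fac[1, 0] == 38.0

    def test_cromer_mann_f0_near_atomic_number(self):
        for el, z in (("C", 6), ("N", 7), ("O", 8), ("ZN", 30)):
            assert cromer_mann(el, np.array([0.0]))[0] == pytest.approx(z, abs=0.1)


class TestWeightedAverage:
    def _curves(self, values):
        q = np.linspace(0.01, 0.3, 10)
        return [ScatteringCurve(q, np.full_like(q, v)) for v in values]

    def test_single_profile_weight_one(self):
        (p,) = self._curves([3.0])
        out = weighted_average_profile([1.0], [p])
        np.testing.assert_allclose(out.I, p.I)

    def test_identical_profiles_any_weights(self):
        p1, p2 = self._curves([2.0, 2.0])
        out = weighted_average_profile([0.3, 0.7], [p1, p2])
        np.testing.assert_allclose(out.I, 2.0)

    def test_convex_combination_values(self):
        p1, p2 = self._curves([1.0, 2.0])
        out = weighted_average_profile([0.25, 0.75], [p1, p2])
        np.testing.assert_allclose(out.I, 1.75)

    def test_weight_sum_violation_rejected(self):
        p1, p2 = self._curves([1.0, 2.0])
        with pytest.raises(ValueError):
            weighted_average_profile([0.5, 0.6], [p1, p2])

    def test_grid_mismatch_rejected(self):
        p1, p2 = self._curves([1.0, 2.0])
        p2.q = p2.q + 0.01
        with pytest.raises(ValueError):
            weighted_average_profile([0.5, 0.5], [p1, p2])


class TestFitToExperiment:
    def _pair(self, scale=1.0, const=0.0, sigma=1.0):
        q = np.linspace(0.01, 0.3, 20)
        I = np.exp(-q ** 2 * 300.0) * 100.0
        comp = ScatteringCurve(q, I)
        exp = ScatteringCurve(q, scale * I + const, np.full_like(q, sigma))
        return comp, exp

    def test_identical_curves(self):
        comp, exp = self._pair()
        fit = fit_to_experiment(comp, exp)
        assert fit.c == pytest.approx(1.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)

    def test_pure_scale(self):
        comp, exp = self._pair(scale=2.0)
        fit = fit_to_experiment(comp, exp)
        assert fit.c == pytest.approx(2.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)
        assert fit.chi2_red == fit.chi2 / fit.n_points

    def test_scale_matches_normal_equations(self):
        q = np.array([0.1, 0.2, 0.3])
        comp = ScatteringCurve(q, np.array([1.0, 2.0, 3.0]))
        exp = ScatteringCurve(q, np.array([2.1, 3.9, 6.0]), np.ones(3))
        fit = fit_to_experiment(comp, exp)
        c_oracle = (comp.I @ exp.I) / (comp.I @ comp.I)
        assert fit.c == pytest.approx(c_oracle, rel=1e-12)

    def test_constant_subtraction_recovers_offset(self):
        comp, exp = self._pair(scale=1.5, const=7.0)
        fit = fit_to_experiment(comp, exp, fit_constant=True)
        assert fit.c == pytest.approx(1.5, rel=1e-8)
        assert fit.constant == pytest.approx(7.0, rel=1e-6)

    def test_chi2_invariant_under_joint_rescaling(self, rng):
        comp, exp = self._pair()
        exp.I = exp.I + rng.normal(scale=1.0, size=len(exp.I))
        fit1 = fit_to_experiment(comp, exp)
        scaled = ScatteringCurve(exp.q, 10.0 * exp.I, 10.0 * exp.sigma)
        fit2 = fit_to_experiment(comp, scaled)
        assert fit1.chi2 == pytest.approx(fit2.chi2, rel=1e-10)

    def test_missing_sigma_is_error(self):
        comp, _ = self._pair()
        with pytest.raises(ValueError):
            fit_to_experiment(comp, comp)


class TestCurveIO:
    def test_roundtrip_with_sigma(self, tmp_path):
        q = np.linspace(0.01, 0.3, 12)
        curve = ScatteringCurve(q, np.exp(-q ** 2), 0.01 * np.ones_like(q))
        p = tmp_path / "curve.dat"
        save_curve(curve, p)
        back = load_curve(p)
        np.testing.assert_allclose(back.q, curve.q)
        np.testing.assert_allclose(back.I, curve.I)
        np.testing.assert_allclose(back.sigma, curve.sigma)

    def test_comment_lines_ignored(self, tmp_path):
        p = tmp_path / "c.dat"
        p.write_text("# header\n0.01 1.0 0.1\n0.02 0.9 0.1\n")
        curve = load_curve(p)
        assert len(curve) == 2 and curve.sigma is not None

    def test_interpolation_refuses_extrapolation(self):
        q = np.linspace(0.1, 0.3, 5)
        curve = ScatteringCurve(q, np.ones_like(q))
        with pytest.raises(ValueError):
            curve.interpolated(np.linspace(0.0, 0.2, 5))
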