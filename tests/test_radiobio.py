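"""EQD2 conversion and the LKB / relative-seriality NTCP models.

Closed-form identities are asserted exactly; non-trivial values are checked
against independent oracles (numerical integration of the probit integral,
extended-precision evaluation via sympy).
"""

import numpy as np
import pytest
from scipy.integrate import quad

from phandose.dvh import compute_dvh
from phandose.radiobio import (
    LKBParams,
    NTCP_ENDPOINTS,
    REGISTRY,
    RSParams,
    effective_dose,
    eqd2,
    lkb_ntcp,
    lkb_ntcp_from_bins,
    ntcp_suite,
    rs_ntcp_from_bins,
    rs_response,
)
from phandose.volumes import DoseGrid, StructureMask

G2 = REGISTRY["lkb"]["G2-LRB"]
RS_G2 = REGISTRY["rs"]["G2-LRB"]


class TestEQD2:
    def test_two_gray_per_fraction_is_fixed_point(self):
        assert eqd2(68.0, 34) == pytest.approx(68.0)

    def test_hypofractionation_hand_arithmetic(self):
        # 74.8 Gy in 34 fractions: d = 2.2 Gy -> EQD2 = 74.8 * 5.2 / 5
        assert eqd2(74.8, 34, alpha_beta=3.0) == pytest.approx(77.792)

    def test_zero_dose(self):
        assert eqd2(0.0, 34) == 0.0

    def test_vectorised_and_domain(self):
        out = eqd2(np.array([0.0, 68.0, 74.8]), 34)
        np.testing.assert_allclose(out, [0.0, 68.0, 77.792])
        with pytest.raises(ValueError):
            eqd2(10.0, 0)
        with pytest.raises(ValueError):
            eqd2(-1.0, 34)


class TestEffectiveDose:
    def test_uniform_dose_for_any_n(self):
        for n in (0.05, 0.19, 1.0, 2.0):
            p = LKBParams(n=n, m=0.32, td50=75.8)
            assert effective_dose(np.array([60.0]), np.array([1.0]), p) == pytest.approx(60.0)

    def test_n_equal_one_is_mean(self, rng):
        d = rng.random(20) * 70
        v = rng.random(20)
        v /= v.sum()
        p = LKBParams(n=1.0, m=0.32, td50=75.8)
        assert effective_dose(d, v, p) == pytest.approx(np.sum(v * d))

    def test_small_n_approaches_max(self, rng):
        # exact limit: Deff -> max * v_max**n as n -> 0, so at n = 0.001 a
        # two-bin curve sits within 0.1 Gy of its maximum; a 30-bin curve
        # carries the (1/30)**n volume factor but still converges
        p = LKBParams(n=0.001, m=0.32, td50=75.8)
        two = effective_dose(np.array([30.0, 70.0]), np.array([0.5, 0.5]), p)
        assert two == pytest.approx(70.0, abs=0.1)
        d = rng.random(30) * 70
        v = np.full(30, 1 / 30)
        got = effective_dose(d, v, p)
        # stable brute-force oracle: factor out the maximum before powering
        oracle = d.max() * np.sum(v * (d / d.max()) ** 1000.0) ** 0.001
        assert got == pytest.approx(oracle, rel=1e-9)
        assert got == pytest.approx(d.max(), rel=0.01)

    def test_two_bin_power_mean_oracle(self):
        # independent high-precision evaluation of the generalised mean
        import sympy

        n = sympy.Rational(19, 100)
        exact = float(
            (sympy.Rational(1, 2) * sympy.Integer(30) ** (1 / n)
             + sympy.Rational(1, 2) * sympy.Integer(70) ** (1 / n)) ** n
        )
        p = LKBParams(n=0.19, m=0.32, td50=75.8)
        got = effective_dose(np.array([30.0, 70.0]), np.array([0.5, 0.5]), p)
        assert got == pytest.approx(exact, rel=1e-9)

    def test_volume_normalisation_enforced(self):
        p = LKBParams(n=0.19, m=0.32, td50=75.8)
        with pytest.raises(ValueError, match="sum to 1"):
            effective_dose(np.array([60.0]), np.array([0.5]), p)


class TestLKB:
    def test_half_probability_at_td50(self):
        for p in REGISTRY["lkb"].values():
            got = lkb_ntcp_from_bins(np.array([p.td50]), np.array([1.0]), p)
            assert abs(got - 0.5) < 1e-9

    def test_uniform_60gy_matches_probit_integration(self):
        # oracle: numerically integrate the standard normal density up to t
        t = (60.0 - G2.td50) / (G2.m * G2.td50)
        oracle, _ = quad(lambda x: np.exp(-x * x / 2) / np.sqrt(2 * np.pi), -np.inf, t)
        got = lkb_ntcp_from_bins(np.array([60.0]), np.array([1.0]), G2)
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(0.257, abs=2e-3)

    def test_strictly_increasing_in_dose(self, rng):
        d = np.sort(rng.random(10)) * 60 + 5
        v = np.full(10, 0.1)
        lo = lkb_ntcp_from_bins(d, v, G2)
        hi = lkb_ntcp_from_bins(d + 5.0, v, G2)
        assert hi > lo


class TestRelativeSeriality:
    def test_response_half_at_d50(self):
        assert rs_response(RS_G2.d50, RS_G2) == pytest.approx(0.5)

    def test_response_vanishes_at_zero_dose(self):
        assert rs_response(0.0, RS_G2) < 1e-18

    def test_response_monotone_and_bounded(self):
        d = np.linspace(0, 150, 200)
        p = rs_response(d, RS_G2)
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p < 1))

    def test_whole_organ_at_d50_collapses_to_half(self):
        got = rs_ntcp_from_bins(np.array([RS_G2.d50]), np.array([1.0]), RS_G2)
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_zero_dose_gives_zero(self):
        got = rs_ntcp_from_bins(np.zeros(3), np.array([0.5, 0.3, 0.2]), RS_G2)
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_three_bin_sympy_oracle(self):
        # independent extended-precision evaluation of the seriality formula
        import sympy

        d50, gamma, s = (sympy.Float(x, 50) for x in (83.6, 1.42, 0.50))
        vols = [sympy.Rational(1, 2), sympy.Rational(3, 10), sympy.Rational(1, 5)]
        doses = [40, 60, 80]
        prod = sympy.Integer(1)
        for v, d in zip(vols, doses):
            pd = 2 ** (-sympy.exp(sympy.exp(gamma) * (1 - d / d50)))
            prod *= (1 - pd**s) ** v
        exact = float(((1 - prod) ** (1 / s)).evalf(50))
        got = rs_ntcp_from_bins(
            np.array([40.0, 60.0, 80.0]), np.array([0.5, 0.3, 0.2]), RSParams(83.6, 1.42, 0.50)
        )
        assert got == pytest.approx(exact, rel=1e-10)


class TestNTCPSuite:
    def _dose_and_rectum(self, rng, scale=1.0):
        vals = rng.random((6, 8, 8)) * 70 * scale
        dose = DoseGrid(values=vals, prescription=74.8, n_fractions=34, spacing=(3, 3, 3))
        m = np.zeros(vals.shape, dtype=np.uint8)
        m[1:5, 2:6, 2:6] = 1
        return dose, StructureMask(roi_name="rectum", values=m, spacing=(3, 3, 3))

    def test_eight_endpoints_in_percent_range(self, rng):
        dose, rectum = self._dose_and_rectum(rng)
        table = ntcp_suite(dose, rectum)
        assert tuple(table) == NTCP_ENDPOINTS
        assert all(0.0 <= v <= 100.0 for v in table.values())

    def test_identical_doses_give_identical_tables(self, rng):
        dose, rectum = self._dose_and_rectum(rng)
        assert ntcp_suite(dose, rectum) == ntcp_suite(dose, rectum)

    def test_bin_refinement_invariance(self, phantom_sample):
        sample, _ = phantom_sample
        coarse = ntcp_suite(sample.dose, sample.masks["rectum"], bin_width=0.1)
        fine = ntcp_suite(sample.dose, sample.masks["rectum"], bin_width=0.05)
        for k in coarse:
            assert abs(coarse[k] - fine[k]) < 0.1  # percentage points

    def test_lkb_ntcp_from_curve_uses_eqd2(self, phantom_sample):
        sample, _ = phantom_sample
        curve = compute_dvh(sample.dose, sample.masks["rectum"])
        direct = lkb_ntcp(curve, G2, sample.dose.n_fractions)
        centers, v = curve.differential()
        keep = v > 0
        expected = lkb_ntcp_from_bins(
            eqd2(centers[keep], sample.dose.n_fractions), v[keep] / v[keep].sum(), G2
        )
        assert direct == pytest.approx(expected, rel=1e-12)


def test_registry_values_are_frozen():
    with pytest.raises(TypeError):
        REGISTRY["lkb"]["G2-LRB"] = None  # type: ignore[index]
    assert (G2.n, G2.m, G2.td50) == (0.19, 0.32, 75.8)
    assert (RS_G2.d50, RS_G2.gamma, RS_G2.s) == (83.6, 1.42, 0.50)
    assert all(p.alpha_beta == 3.0 for p in REGISTRY["lkb"].values())
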