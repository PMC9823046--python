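"""Implied-moment structure: reduced form, covariance algebra, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrdoc2 import (
    DZ,
    MZ,
    ParamVector,
    StudyDesign,
    implied_covariance,
    implied_moments,
    phenotype_summary,
    reduced_form,
    sample_pairs,
)
from conftest import random_admissible_theta


class TestReducedForm:
    def test_no_causation_passes_loadings_through(self):
        theta = ParamVector(b1=0.3, b3=0.4)
        instrument_map, mixing = reduced_form(theta)
        assert np.allclose(mixing, np.eye(2))
        assert np.allclose(instrument_map, [[0.3, 0.0], [0.0, 0.4]])

    def test_closed_form_with_reciprocal_loop(self):
        # g1 = g2 = sqrt(0.06): 1 - g1*g2 = 0.94
        g = math.sqrt(0.06)
        b = math.sqrt(0.075)
        theta = ParamVector(g1=g, g2=g, b1=b, b3=b)
        instrument_map, _ = reduced_form(theta)
        assert instrument_map[:, 0] == pytest.approx([b / 0.94, g * b / 0.94])

    def test_singular_loop_raises(self):
        with pytest.raises(ValueError, match="reduced form"):
            reduced_form(ParamVector(g1=2.0, g2=0.5))


class TestImpliedMoments:
    def test_pure_environment_null_model(self):
        theta = ParamVector()  # e1 = e2 = 1, everything else off
        for zyg, ps_cross in ((MZ, 1.0), (DZ, 0.5)):
            mom = implied_moments(theta, zyg)
            cov = mom.covariance
            assert np.allclose(cov[:2, :2], np.eye(2))          # unit phenotypes
            assert np.allclose(cov[:2, 4:6], 0.0)               # no Ph cross-twin
            assert cov[2, 6] == pytest.approx(ps_cross)          # PS1 cross-twin
            assert cov[3, 7] == pytest.approx(ps_cross)
            assert np.allclose(mom.mean, 0.0)

    def test_phenotype_variance_closed_form(self, theta_high_power):
        # hand algebra: Ph1 = (U1 + b1 PS1 + g2 (U2 + b3 PS2)) / (1 - g1 g2)
        # with unit-variance latent parts U and independent unit PSs:
        # Var(Ph1) = (1 + b1^2) (1 + g2^2) / (1 - g1 g2)^2
        d = 1.0 - theta_high_power.g1 * theta_high_power.g2
        expected_var = 1.075 * (1 + 0.06) / d**2
        expected_cov = 1.075 * (theta_high_power.g1 + theta_high_power.g2) / d**2
        cov = implied_covariance(theta_high_power, MZ)
        assert cov[0, 0] == pytest.approx(expected_var, abs=1e-12)
        assert cov[0, 1] == pytest.approx(expected_cov, abs=1e-12)
        assert cov[0, 0] == pytest.approx(1.28961, abs=5e-6)
        assert cov[0, 1] == pytest.approx(0.59602, abs=5e-6)

    def test_within_twin_block_is_zygosity_invariant(self, theta_low_power):
        mz = implied_moments(theta_low_power, MZ)
        dz = implied_moments(theta_low_power, DZ)
        assert np.allclose(mz.within_twin, dz.within_twin, atol=1e-12)
        assert np.allclose(
            mz.covariance[4:, 4:], mz.covariance[:4, :4], atol=1e-12
        )

    def test_instrument_outcome_covariance_closed_form(self):
        g1, b1 = 0.25, 0.3
        base = ParamVector(b1=b1, b3=0.2)
        assert implied_covariance(base, MZ)[2, 1] == pytest.approx(0.0, abs=1e-14)
        theta = base.replace(g1=g1, g2=0.1)
        expected = g1 * b1 * theta.sigma_x**2 / (1 - theta.g1 * theta.g2)
        assert implied_covariance(theta, MZ)[2, 1] == pytest.approx(expected)

    def test_symmetry_and_psd_across_random_points(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            theta = random_admissible_theta(rng)
            for zyg in (MZ, DZ):
                cov = implied_moments(theta, zyg).covariance
                assert np.abs(cov - cov.T).max() < 1e-12
                assert np.linalg.eigvalsh(cov)[0] > -1e-10

    @given(
        a=st.floats(0.1, 0.7), c=st.floats(0.1, 0.6),
        g1=st.floats(-0.3, 0.3), g2=st.floats(-0.3, 0.3),
        b1=st.floats(0.0, 0.5), ra=st.floats(-0.5, 0.5),
        re=st.floats(-0.5, 0.5), rf=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_psd_property_standardized_ae(self, a, c, g1, g2, b1, ra, re, rf):
        theta = ParamVector.standardized(
            a1=a, c1=c, a2=a, c2=c, g1=g1, g2=g2, b1=b1, b3=b1,
            ra=ra, rc=0.2, re=re, rf=rf,
        )
        for zyg in (MZ, DZ):
            cov = implied_covariance(theta, zyg)
            assert np.abs(cov - cov.T).max() < 1e-12
            assert np.linalg.eigvalsh(cov)[0] > -1e-10

    def test_reduces_to_classic_doc_without_instruments(self):
        """b1 = b3 = 0: the phenotype block equals the two-phenotype
        direction-of-causation structure built independently from scalar
        path algebra."""
        theta = ParamVector(
            ra=0.3, rc=0.2, re=0.1, a1=0.5, c1=0.4, e1=math.sqrt(1 - 0.25 - 0.16),
            a2=0.6, c2=0.3, e2=math.sqrt(1 - 0.36 - 0.09), g1=0.2, g2=0.1,
        )
        r = np.array([[1.0, theta.g2], [theta.g1, 1.0]]) / (1 - theta.g1 * theta.g2)

        def factor_cov(l1, l2, rho):
            return np.array([[l1 * l1, l1 * l2 * rho], [l1 * l2 * rho, l2 * l2]])

        amat = factor_cov(theta.a1, theta.a2, theta.ra)
        cmat = factor_cov(theta.c1, theta.c2, theta.rc)
        emat = factor_cov(theta.e1, theta.e2, theta.re)
        within = r @ (amat + cmat + emat) @ r.T
        for zyg in (MZ, DZ):
            cross = r @ (zyg.genetic_share * amat + cmat) @ r.T
            cov = implied_covariance(theta, zyg)
            ph = np.ix_([0, 1, 4, 5], [0, 1, 4, 5])
            expected = np.block([[within, cross], [cross.T, within]])
            assert np.allclose(cov[ph], expected, atol=1e-12)

    def test_monte_carlo_sample_covariance_matches(self):
        rng = np.random.default_rng(11)
        theta = random_admissible_theta(rng)
        n = 200_000
        table = sample_pairs(theta, StudyDesign(n, n, seed=5, mode="stochastic"))
        for zyg in (MZ, DZ):
            rows = table[table["zygosity"] == zyg.label]
            data = rows.iloc[:, 2:].to_numpy()
            s = np.cov(data, rowvar=False)
            sigma = implied_covariance(theta, zyg)
            se = np.sqrt(
                (np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n
            )
            assert (np.abs(s - sigma) <= 4 * se).all()


class TestPhenotypeSummary:
    def test_high_power_cell_r2(self, theta_high_power):
        s = phenotype_summary(theta_high_power)
        assert s.r2_ph1_on_ps1 == pytest.approx(0.066, abs=5e-4)
        assert s.r2_ph2_on_ps2 == pytest.approx(0.066, abs=5e-4)
        assert s.r2_ph2_ph1 == pytest.approx(0.214, abs=5e-4)

    def test_confounded_cell_r2(self, theta_low_power):
        s = phenotype_summary(theta_low_power)
        assert s.r2_ph2_ph1 == pytest.approx(0.465, abs=5e-4)
        assert s.r2_ph1_on_ps1 == pytest.approx(0.025, abs=5e-4)
        assert s.r2_ph2_on_ps2 == pytest.approx(0.045, abs=5e-4)

    def test_no_instrument_path_no_r2(self):
        theta = ParamVector(b1=0.0, b3=0.3, rf=0.0)
        assert phenotype_summary(theta).r2_ph1_on_ps1 == 0.0

    def test_zero_variance_raises(self):
        broken = ParamVector(e1=0.0, e2=1.0)  # Ph1 has no variance source
        with pytest.raises(ValueError, match="variance"):
            phenotype_summary(broken)
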