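"""Factorial designs, NCP regression decomposition, required-N curves."""

import math

import numpy as np
import pytest

from mrdoc2 import (
    FactorialDesign,
    FreePattern,
    ParamVector,
    PowerCell,
    StudyDesign,
    design1,
    design2,
    design3,
    phenotype_summary,
    power_from_ncp,
    regress_ncp,
    required_n_curve,
    run_design,
    single_cell,
    cells_to_frame,
)
from mrdoc2.model import PhenotypeSummary
from conftest import sqrt


class TestFactorialDesigns:
    @pytest.mark.parametrize(
        "factory, n_cells", [(design1, 4096), (design2, 8748), (design3, 256)]
    )
    def test_cell_counts(self, factory, n_cells):
        assert factory().n_cells == n_cells

    def test_cell_theta_matches_iteration_order(self):
        design = design2()
        themap = dict(design.iter_cells())
        for index in (0, 1, 137, 8747):
            assert design.cell_theta(index) == themap[index]
        with pytest.raises(IndexError):
            design.cell_theta(8748)

    def test_levels_are_signed_square_roots(self):
        d3 = design3()
        assert d3.factors["b1"] == pytest.approx(
            [-math.sqrt(0.075), -math.sqrt(0.03), math.sqrt(0.03), math.sqrt(0.075)]
        )
        # derived unique-environment loading keeps unit latent variance
        theta = d3.cell_theta(0)
        assert theta.a1**2 + theta.e1**2 == pytest.approx(1.0)
        assert theta.rc == 0.0 and theta.c1 == 0.0

    def test_subsample_deterministic(self):
        d = design1()
        assert d.subsample(10, seed=3) == d.subsample(10, seed=3)
        assert len(set(d.subsample(10, seed=3))) == 10


class TestSingleCell:
    def test_joint_ncp_dominates_marginals(self, theta_moderate_power, ae_pattern):
        cell = single_cell(theta_moderate_power, ae_pattern)
        assert cell.error is None
        assert cell.ncp_joint >= max(cell.ncp_g1, cell.ncp_g2) - 1e-4
        for p in (cell.pow_g1, cell.pow_g2, cell.pow_joint):
            assert 0.05 - 1e-9 <= p <= 1.0

    def test_trait_swap_symmetry(self, ae_pattern):
        theta = ParamVector.standardized(
            b1=sqrt(0.075), b3=sqrt(0.03), g1=sqrt(0.05), g2=sqrt(0.02),
            ra=0.3, re=0.2, rf=0.25, a1=sqrt(0.4), a2=sqrt(0.2),
        )
        swapped = ParamVector.standardized(
            b1=theta.b3, b3=theta.b1, g1=theta.g2, g2=theta.g1,
            ra=theta.ra, re=theta.re, rf=theta.rf,
            a1=theta.a2, a2=theta.a1,
        )
        c1 = single_cell(theta, ae_pattern, tests=("g1", "g2"))
        c2 = single_cell(swapped, ae_pattern, tests=("g1", "g2"))
        assert c1.ncp_g1 == pytest.approx(c2.ncp_g2, abs=1e-4)
        assert c1.ncp_g2 == pytest.approx(c2.ncp_g1, abs=1e-4)

    def test_ncp_invariant_to_outcome_side_paths(self, theta_high_power, ae_pattern):
        """The g1-test NCP barely moves when b3 and g2 change alone
        (several exemplary rows share one printed NCP)."""
        ref = single_cell(theta_high_power, ae_pattern, tests=("g1",)).ncp_g1
        other = ParamVector.standardized(
            b1=theta_high_power.b1, b3=sqrt(0.025),
            g1=theta_high_power.g1, g2=sqrt(0.02),
            a1=sqrt(0.10), a2=sqrt(0.10),
        )
        alt = single_cell(other, ae_pattern, tests=("g1",)).ncp_g1
        assert abs(alt - ref) / ref < 0.005


def _fake_cells(thetas, ncps):
    summary = PhenotypeSummary(0.0, 0.0, 0.0)
    return [
        PowerCell(i, th, ncp, ncp, ncp, 0.5, 0.5, 0.5, summary)
        for i, (th, ncp) in enumerate(zip(thetas, ncps))
    ]


class TestRegressNcp:
    def test_beta_squared_equals_anova_share_on_orthogonal_design(self):
        """On a balanced two-level factorial the squared standardized OLS
        coefficients must reproduce the per-factor sum-of-squares shares
        from a direct ANOVA decomposition."""
        design = FactorialDesign(
            factors={
                "b1": [sqrt(0.025), sqrt(0.075)],
                "g1": [sqrt(0.02), sqrt(0.06)],
                "re": [0.0, 0.5],
            },
            fixed={"rc": 0.0, "c1": 0.0, "c2": 0.0, "ra": 0.25, "rf": 0.25,
                   "b3": sqrt(0.05), "g2": sqrt(0.02),
                   "a1": sqrt(0.25), "a2": sqrt(0.25)},
        )
        cells = run_design(design, tests=("g1",))
        assert all(c.error is None for c in cells)
        summary = regress_ncp(cells, "g1")
        y = np.array([c.ncp_g1 for c in cells])
        tss = ((y - y.mean()) ** 2).sum()
        for name in ("b1", "g1", "re"):
            x = np.array([getattr(c.theta, name) for c in cells])
            hi = y[x == x.max()].mean()
            lo = y[x == x.min()].mean()
            # direct ANOVA share: n/2 * ((hi-mean)^2 + (lo-mean)^2) / TSS
            share = (len(y) / 2) * ((hi - y.mean()) ** 2 + (lo - y.mean()) ** 2) / tss
            assert summary.beta_squared[name] == pytest.approx(share, abs=1e-10)

    def test_constant_response_gives_zero_shares(self):
        thetas = [
            ParamVector.standardized(b1=b, g1=0.2, a1=0.5, a2=0.5)
            for b in (0.1, 0.2, 0.3, 0.4)
        ]
        summary = regress_ncp(_fake_cells(thetas, [2.0] * 4), "g1")
        assert summary.total_r2 == 0.0
        assert all(v == 0.0 for v in summary.beta_squared.values())

    def test_collinear_factors_rejected(self):
        thetas = [
            ParamVector.standardized(b1=b, b3=b, a1=0.5, a2=0.5)  # lockstep
            for b in (0.1, 0.2, 0.3, 0.4)
        ]
        with pytest.raises(ValueError, match="collinear"):
            regress_ncp(_fake_cells(thetas, [1.0, 2.0, 3.0, 4.0]), "g1")

    def test_quadratic_terms_reported_separately(self):
        design = FactorialDesign(
            factors={"b1": [sqrt(0.01), sqrt(0.04), sqrt(0.075)],
                     "g1": [sqrt(0.01), sqrt(0.04), sqrt(0.06)]},
            fixed={"rc": 0.0, "c1": 0.0, "c2": 0.0, "ra": 0.0, "re": 0.0,
                   "rf": 0.0, "b3": sqrt(0.05), "g2": sqrt(0.02),
                   "a1": sqrt(0.25), "a2": sqrt(0.25)},
        )
        cells = run_design(design, tests=("g1",))
        lin = regress_ncp(cells, "g1", order=1)
        quad = regress_ncp(cells, "g1", order=2)
        assert quad.quadratic_r2_gain is not None
        assert quad.quadratic_r2_gain >= -1e-12
        assert lin.quadratic_r2_gain is None


@pytest.fixture(scope="module")
def scenario_alcohol_heart():
    """Exposure with a^2=0.49, c^2=0.10; outcome with a^2=0.22, c^2=0;
    b3 = g1 = g2 = sqrt(0.05), ra=0.3, rc=0.25, re=0.3, rf=0.25."""
    return ParamVector.standardized(
        b3=sqrt(0.05), g1=sqrt(0.05), g2=sqrt(0.05),
        ra=0.3, rc=0.25, re=0.3, rf=0.25,
        a1=sqrt(0.49), c1=sqrt(0.10), a2=sqrt(0.22),
    )


@pytest.fixture(scope="module")
def curve_points(scenario_alcohol_heart):
    return required_n_curve(scenario_alcohol_heart, [0.01, 0.02, 0.05])


class TestRequiredN:
    def test_required_n_monotone_and_bracketing(self, curve_points):
        ns = [p.n_pairs_80 for p in curve_points]
        assert ns == sorted(ns, reverse=True)
        for p in curve_points:
            # independent check: direct power evaluation brackets the target
            assert power_from_ncp(p.n_pairs_80 * p.ncp_per_pair, 1) >= 0.80
            assert power_from_ncp((p.n_pairs_80 - 2) * p.ncp_per_pair, 1) < 0.80

    def test_required_n_frozen_regression_values(self, curve_points):
        assert [p.n_pairs_80 for p in curve_points] == [10176, 5094, 1948]

    def test_solved_b1_reproduces_target_r2(self, scenario_alcohol_heart, curve_points):
        for p in curve_points:
            implied = phenotype_summary(
                scenario_alcohol_heart.replace(b1=p.b1)
            ).r2_ph1_on_ps1
            assert implied == pytest.approx(p.r2_instrument, abs=1e-10)


class TestRunDesign:
    def test_errors_recorded_not_raised(self, ae_pattern):
        frame_cells = run_design(
            design2(), StudyDesign(50, 50), cells=[0, 1], tests=("g1",)
        )
        assert len(frame_cells) == 2
        frame = cells_to_frame(frame_cells)
        assert {"ncp_g1", "pow_g1", "r2_ph1_on_ps1"} <= set(frame.columns)
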