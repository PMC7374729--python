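"""Unit tests for the two-state LEM denaturation analysis."""

import numpy as np
import pytest

from stabscan import (
    Baselines,
    DenaturationCurve,
    FitConfig,
    FreeEnergySeries,
    R_KCAL,
    analyze_curve,
    ddg_relative,
    fit_lem,
    folded_fraction,
    folding_constant,
    free_energy,
)
from stabscan.denaturation import TwoStateFit, estimate_baselines
from stabscan.errors import (
    DegenerateBaselineError,
    DomainError,
    InsufficientDataError,
    NoTransitionDataError,
    StageError,
)

from conftest import fit_noiseless, ols_closed_form

RT = R_KCAL * 298.15  # ~0.59253 kcal/mol


def make_curve(conc, theta, sample_id="s"):
    return DenaturationCurve(sample_id, tuple(conc), tuple(theta))


class TestCurveValidation:
    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            make_curve([0, 1, 2, 3, 4], [0, 1, 2, 3])

    def test_rejects_non_increasing_concentrations(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_curve([0, 1, 1, 3, 4], [1, 2, 3, 4, 5])

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError, match="at least 5"):
            make_curve([0, 1, 2, 3], [1, 2, 3, 4])


class TestFoldedFraction:
    @pytest.mark.parametrize(
        "theta_i, expected_alpha, expected_retained",
        [
            (-20.0, 1.0, False),   # fully folded endpoint
            (-5.0, 0.0, False),    # fully unfolded endpoint
            (-12.5, 0.5, True),    # exact midpoint
        ],
    )
    def test_normalization(self, theta_i, expected_alpha, expected_retained):
        curve = make_curve(
            [0, 1, 2, 3, 4], [-20.0, -18.0, theta_i, -6.0, -5.0]
        )
        fs = folded_fraction(curve, Baselines(-20.0, -5.0))
        assert fs.fractions[2] == pytest.approx(expected_alpha)
        assert fs.retained[2] is expected_retained

    def test_identical_baselines_rejected(self):
        with pytest.raises(DegenerateBaselineError):
            Baselines(-10.0, -10.0)

    def test_no_transition_data(self):
        # every point sits on the folded baseline
        curve = make_curve([0, 1, 2, 3, 4], [-20.0] * 5)
        with pytest.raises(NoTransitionDataError):
            folded_fraction(curve, Baselines(-20.0, -5.0))

    def test_scale_invariance(self):
        """alpha is invariant under affine rescaling of the instrument units."""
        conc = [0, 1, 2, 3, 4]
        theta = [-20.0, -16.0, -12.0, -8.0, -5.0]
        a = folded_fraction(make_curve(conc, theta), Baselines(-20.0, -5.0))
        scaled = [3.0 * t + 7.0 for t in theta]
        b = folded_fraction(make_curve(conc, scaled), Baselines(-53.0, -8.0))
        assert np.allclose(a.fractions, b.fractions)


class TestFoldingConstantAndFreeEnergy:
    @pytest.mark.parametrize("alpha, expected_k", [(0.5, 1.0), (0.9, 9.0), (0.25, 1 / 3)])
    def test_folding_constant_values(self, alpha, expected_k):
        curve = make_curve([0, 1, 2, 3, 4], [-20, -18, -5 - 15 * alpha, -6, -5])
        fs = folded_fraction(curve, Baselines(-20.0, -5.0))
        ks = folding_constant(fs)
        i = ks.concentrations.index(2.0)
        assert ks.folding_constants[i] == pytest.approx(expected_k)

    @pytest.mark.parametrize(
        "k, expected_dg",
        [
            (1.0, 0.0),
            (9.0, -RT * np.log(9)),          # ~ -1.302 kcal/mol
            (np.exp(-1.0), RT),              # ~ +0.5925 kcal/mol
        ],
    )
    def test_free_energy_values(self, k, expected_dg):
        series = FreeEnergySeries("s", (1.0,), (k,))
        out = free_energy(series, temperature_K=298.15)
        assert out.free_energies[0] == pytest.approx(expected_dg, abs=1e-4)

    def test_free_energy_derived_magnitudes(self):
        # frozen values from direct evaluation of -R*T*ln K
        series = FreeEnergySeries("s", (1.0, 2.0), (9.0, np.exp(-1.0)))
        out = free_energy(series, temperature_K=298.15)
        assert out.free_energies[0] == pytest.approx(-1.3019, abs=1e-3)
        assert out.free_energies[1] == pytest.approx(0.59253, abs=1e-4)

    def test_non_positive_k_rejected(self):
        with pytest.raises(DomainError):
            free_energy(FreeEnergySeries("s", (1.0,), (0.0,)))


class TestFitLem:
    def test_exact_line(self):
        # collinear points: dG = -5.3 + 1.7 c
        series = FreeEnergySeries(
            "s", (1.0, 2.0, 3.0), (1.0, 1.0, 1.0),
            free_energies=(-3.6, -1.9, -0.2),
        )
        fit = fit_lem(series)
        assert fit.dg0 == pytest.approx(-5.3)
        assert fit.m_value == pytest.approx(1.7)
        assert fit.c_half == pytest.approx(5.3 / 1.7)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points_used == 3
        assert not fit.noncooperative

    def test_insufficient_points(self):
        series = FreeEnergySeries(
            "s", (1.0, 2.0), (1.0, 1.0), free_energies=(-3.6, -1.9)
        )
        with pytest.raises(InsufficientDataError):
            fit_lem(series)

    def test_narrow_span_rejected(self):
        series = FreeEnergySeries(
            "s", (1.0, 1.05, 1.1), (1.0,) * 3, free_energies=(0.1, 0.2, 0.3)
        )
        with pytest.raises(InsufficientDataError, match="span"):
            fit_lem(series)

    def test_negative_slope_flagged_not_fatal(self):
        series = FreeEnergySeries(
            "s", (1.0, 2.0, 3.0), (1.0,) * 3, free_energies=(0.2, -1.9, -3.6)
        )
        fit = fit_lem(series)
        assert fit.noncooperative

    def test_ols_matches_closed_form_oracle(self):
        """fit_lem agrees with an independent normal-equations solution."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(3, 8)
            c = np.sort(rng.uniform(0, 5, size=n))
            while c.max() - c.min() <= 0.2:
                c = np.sort(rng.uniform(0, 5, size=n))
            dg = rng.normal(0, 2, size=n)
            series = FreeEnergySeries(
                "s", tuple(c), tuple(np.ones(n)), free_energies=tuple(dg)
            )
            fit = fit_lem(series)
            b0, b1 = ols_closed_form(c, dg)
            assert fit.dg0 == pytest.approx(b0, abs=1e-10)
            assert fit.m_value == pytest.approx(b1, abs=1e-10)

    def test_c_half_zeroes_the_fitted_line(self):
        fit, _ = fit_noiseless(-5.3, 1.7, "WT")
        assert fit.dg_at(fit.c_half) == pytest.approx(0.0, abs=1e-12)


class TestDdgRelative:
    def test_self_is_zero(self):
        fit, _ = fit_noiseless(-5.3, 1.7)
        assert ddg_relative(fit, fit).ddg_experimental == 0.0

    def test_antisymmetry_and_additivity(self):
        a, _ = fit_noiseless(-5.3, 1.7, "A")
        b, _ = fit_noiseless(-3.0, 1.3, "B")
        c, _ = fit_noiseless(-1.5, 0.6, "C")
        ab = ddg_relative(a, b).ddg_experimental
        ba = ddg_relative(b, a).ddg_experimental
        bc = ddg_relative(b, c).ddg_experimental
        ac = ddg_relative(a, c).ddg_experimental
        assert ab == pytest.approx(-ba)
        assert ab + bc == pytest.approx(ac)

    def test_destabilized_mutant_is_positive(self):
        wt = TwoStateFit("WT", -5.3, 1.7, 3.1, 0.1, 0.1, 10, 1.0)
        mut = TwoStateFit("I738T", -3.0, 1.3, 2.3, 0.1, 0.1, 10, 1.0)
        assert ddg_relative(mut, wt).ddg_experimental == pytest.approx(2.3)


class TestAnalyzeCurve:
    def test_audit_accounts_for_every_point(self):
        fit, audit = fit_noiseless(-2.2, 1.1, "C807Y")
        assert len(audit) == 21
        assert audit["retained"].sum() == fit.n_points_used
        # excluded points keep their alpha but have no K / dG
        excluded = audit[~audit["retained"]]
        assert excluded["K"].isna().all()
        assert excluded["alpha"].notna().all()

    def test_all_folded_curve_fails_with_stage_name(self):
        curve = make_curve([0, 1, 2, 3, 4], [-20.0] * 5)
        with pytest.raises(StageError, match="folded_fraction"):
            analyze_curve(curve, FitConfig(theta_folded=-20.0, theta_unfolded=-5.0))

    def test_baseline_estimation_from_flat_regions(self):
        # plateau at both ends: estimated baselines equal the plateau means
        conc = [0.0, 0.1, 0.2, 1.5, 2.0, 2.5, 5.0, 5.5]
        theta = [-20.0, -20.2, -19.8, -15.0, -12.5, -10.0, -5.1, -4.9]
        curve = make_curve(conc, theta)
        baselines = estimate_baselines(curve)
        assert baselines.theta_folded == pytest.approx(-20.0)
        assert baselines.theta_unfolded == pytest.approx(-5.0)

    def test_partial_baseline_override_rejected(self):
        curve = make_curve([0, 1, 2, 3, 5], [-20, -15, -12.5, -8, -5])
        with pytest.raises(StageError):
            analyze_curve(curve, FitConfig(theta_folded=-20.0))

    def test_noisy_recovery_mean_within_tolerance(self):
        """With 2%-of-span Gaussian noise, the mean recovered dG0 over 50
        replicate curves stays within 0.15 kcal/mol of the truth."""
        truth_dg0, truth_m = -5.3, 1.7
        recovered = []
        for seed in range(50):
            fit, _ = fit_noiseless(
                truth_dg0, truth_m, noise_sd=0.30, seed=seed
            )
            recovered.append(fit.dg0)
        assert abs(np.mean(recovered) - truth_dg0) < 0.15
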