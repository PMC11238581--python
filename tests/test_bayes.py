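import math

import numpy as np
import pandas as pd
import pytest

from vesifit.bayes import (
    Posterior,
    PriorSpec,
    SamplerConfig,
    infer_posterior,
    log_likelihood,
    summarize_posterior,
)
from vesifit.binding import BindingCurve, EquilibriumParams, TitrationPoint, \
    equilibrium_fraction_bound
from vesifit.errors import ConfigurationError, InvalidInputError

from oracles import normal_loglik

TRUTH = EquilibriumParams(k_d=5e-9, a=1e-4, b=35)
PROTEIN = 2e-6
RF, RB = 12.3, 16.3


def curve_from_fractions(fractions, lipids, r_free=RF, r_bound=RB, protein=PROTEIN):
    """Binding curve whose radii are the exact linear image of the fractions,
    so the linear conversion in the likelihood is an exact inverse."""
    pts = tuple(
        TitrationPoint(l, r_free + f * (r_bound - r_free)) for l, f in zip(lipids, fractions)
    )
    return BindingCurve(pts, protein_total=protein, r_free=r_free, r_bound=r_bound)


def synthetic_curve(params=TRUTH, n=16, noise=0.0, seed=0, protein=PROTEIN):
    lipids = np.geomspace(1e-6, 2e-3, n)
    f = equilibrium_fraction_bound(params, lipids, protein)
    if noise:
        f = np.clip(f + np.random.default_rng(seed).normal(0, noise, n), 0, 1)
    return curve_from_fractions(f, lipids, protein=protein)


class TestLogLikelihood:
    def test_zero_residual_closed_form(self):
        curve = synthetic_curve()
        sigma = 0.05
        n = len(curve.points)
        ll = log_likelihood(curve, TRUTH, sigma)
        assert ll == pytest.approx(n * math.log(1.0 / (sigma * math.sqrt(2 * math.pi))), rel=1e-9)

    def test_sigma_scaling_analytic(self):
        wrong = EquilibriumParams(k_d=5e-8, a=1e-4, b=35)
        curve = synthetic_curve()
        fobs = np.array([p.apparent_radius for p in curve.points])
        fobs = (fobs - RF) / (RB - RF)
        fmod = equilibrium_fraction_bound(wrong, curve.lipid_totals, PROTEIN)
        ssr = float(np.sum((fobs - fmod) ** 2))
        n = len(curve.points)
        for s1, s2 in ((0.02, 0.04), (0.1, 0.2)):
            delta = log_likelihood(curve, wrong, s2) - log_likelihood(curve, wrong, s1)
            expected = -0.5 * ssr * (1 / s2**2 - 1 / s1**2) - n * math.log(s2 / s1)
            assert delta == pytest.approx(expected, rel=1e-9)

    def test_against_per_point_oracle(self):
        rng = np.random.default_rng(3)
        lipids = np.geomspace(1e-6, 1e-3, 6)
        f = np.clip(
            equilibrium_fraction_bound(TRUTH, lipids, PROTEIN) + rng.normal(0, 0.05, 6), 0, 1
        )
        curve = curve_from_fractions(f, lipids)
        fmod = equilibrium_fraction_bound(TRUTH, lipids, PROTEIN)
        oracle = normal_loglik(f - fmod, 0.07)
        assert log_likelihood(curve, TRUTH, 0.07) == pytest.approx(oracle, rel=1e-9)

    def test_calibrated_mode_requires_calibration(self):
        with pytest.raises(ConfigurationError):
            log_likelihood(synthetic_curve(), TRUTH, 0.05, conversion="calibrated")

    def test_sigma_positive_required(self):
        with pytest.raises(InvalidInputError):
            log_likelihood(synthetic_curve(), TRUTH, 0.0)


class TestInference:
    def test_noise_free_recovery_point_mass_b(self):
        """Dense noise-free curve pins log K_d at the truth."""
        curve = synthetic_curve(n=16)
        priors = PriorSpec(b_weights={35: 1.0})
        post = infer_posterior(curve, priors, seed=5, conversion="linear")
        median = np.median(post.draws["log10_kd"])
        assert abs(median - math.log10(TRUTH.k_d)) < 0.05

    def test_flat_data_pushes_kd_to_upper_bound(self):
        """No binding signal: K_d runs to the weakest allowed value.

        The stoichiometry prior is held at the known value so the absence
        of signal is attributed to affinity alone.
        """
        lipids = np.geomspace(1e-6, 2e-3, 12)
        curve = curve_from_fractions(np.zeros(12), lipids)
        priors = PriorSpec(
            b_weights={35: 1.0}, log10_a_bounds=(-4.01, -3.99)
        )
        post = infer_posterior(curve, priors, seed=5, conversion="linear")
        top_decade = np.mean(post.draws["log10_kd"] > priors.log10_kd_bounds[1] - 1.0)
        assert top_decade >= 0.9
        assert post.diagnostics["boundary_pileup"]["log10_kd"]

    def test_seed_reproducibility(self):
        curve = synthetic_curve(noise=0.03, seed=12, n=12)
        priors = PriorSpec.with_oligomer_b()
        m = []
        for seed in (101, 202):
            post = infer_posterior(curve, priors, seed=seed, conversion="linear")
            m.append(np.median(post.draws["log10_kd"]))
        assert abs(m[0] - m[1]) < 0.05
        # identical seed is bit-for-bit deterministic
        p1 = infer_posterior(curve, priors, seed=303, conversion="linear")
        p2 = infer_posterior(curve, priors, seed=303, conversion="linear")
        pd.testing.assert_frame_equal(p1.draws, p2.draws)

    def test_unit_reparameterization_invariance(self):
        """Expressing lipid in different units with consistently shifted
        priors shifts log a by the same constant and changes nothing else."""
        lipids = np.geomspace(1e-6, 2e-3, 12)
        f = equilibrium_fraction_bound(TRUTH, lipids, PROTEIN)
        f = np.clip(f + np.random.default_rng(1).normal(0, 0.03, 12), 0, 1)
        shift = 3.0  # lipid in mM-equivalents
        c1 = curve_from_fractions(f, lipids)
        c2 = curve_from_fractions(f, lipids * 10**shift)
        pr1 = PriorSpec(b_weights={35: 1.0})
        pr2 = PriorSpec(
            b_weights={35: 1.0},
            log10_a_bounds=(pr1.log10_a_bounds[0] - shift, pr1.log10_a_bounds[1] - shift),
        )
        p1 = infer_posterior(c1, pr1, seed=9, conversion="linear")
        p2 = infer_posterior(c2, pr2, seed=9, conversion="linear")
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(p1.draws["log10_kd"], q) == pytest.approx(
                np.quantile(p2.draws["log10_kd"], q), abs=0.05
            )
            assert np.quantile(p1.draws["log10_a"], q) - shift == pytest.approx(
                np.quantile(p2.draws["log10_a"], q), abs=0.05
            )

    def test_point_mass_b_matches_monomer_machinery(self):
        """b marginalization with a one-point prior equals the plain model."""
        from vesifit.bayes import _PosteriorDensity

        curve = synthetic_curve(noise=0.02, seed=4)
        fobs = (np.array([p.apparent_radius for p in curve.points]) - RF) / (RB - RF)
        dens = _PosteriorDensity(fobs, curve.lipid_totals, PROTEIN, PriorSpec(b_weights={35: 1.0}))
        theta = np.array([[math.log10(TRUTH.k_d), math.log10(TRUTH.a), 0.05]])
        direct = log_likelihood(curve, TRUTH, 0.05)
        assert dens(theta)[0] == pytest.approx(direct, rel=1e-12)


class TestSummaries:
    def _toy_posterior(self, draws):
        return Posterior(
            draws=draws, diagnostics={"converged": True},
            b_pmf={35: 1.0}, priors=PriorSpec(b_weights={35: 1.0}),
        )

    def test_per_draw_reciprocal_convention(self):
        """lipids/site is summarized per draw, not as 1/summary(a)."""
        rng = np.random.default_rng(0)
        n = 4001  # odd, so the sample median is a single draw
        la = rng.normal(-4, 1.0, n)  # strongly skewed a posterior
        draws = pd.DataFrame(
            {"log10_kd": rng.normal(-8, 0.1, n), "log10_a": la,
             "b": 35, "sigma": 0.03}
        )
        s = summarize_posterior(self._toy_posterior(draws))
        per_draw = np.median(10.0 ** (-la))
        assert s.loc["lipids_per_site", "median"] == pytest.approx(per_draw, rel=1e-9)
        # medians commute with monotone maps, so this equals 1/median(a)...
        assert s.loc["lipids_per_site", "median"] == pytest.approx(
            1.0 / 10.0 ** np.median(la), rel=1e-9
        )
        # ...but moment-based summaries do not: 1/mean(a) is far off
        mean_based = 1.0 / np.mean(10.0 ** la)
        assert abs(np.mean(10.0 ** (-la)) - mean_based) / mean_based > 0.5

    def test_symmetric_posterior_median_near_center(self):
        rng = np.random.default_rng(2)
        draws = pd.DataFrame(
            {"log10_kd": rng.normal(-8.3, 0.2, 8000), "log10_a": rng.normal(-4, 0.1, 8000),
             "b": 35, "sigma": 0.03}
        )
        s = summarize_posterior(self._toy_posterior(draws))
        assert math.log10(s.loc["kd_molar", "median"]) == pytest.approx(-8.3, abs=0.02)

    def test_empty_draws_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_posterior(self._toy_posterior(pd.DataFrame()))
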