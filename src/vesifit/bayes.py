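"""Bayesian inference of binding affinity and stoichiometry from a titration.

The model: observed bound fractions (converted from apparent radii via the
linear or calibrated conversion) are independent normal around the
two-state equilibrium prediction, with the noise scale σ inferred.  Priors
are flat in log₁₀-space for K_d and a, flat in linear space for σ on
(0, σ_max], and a discrete distribution over the subunit count b (a point
mass at 1 for monomeric protein; an empirical or uniform distribution over
the oligomer size range otherwise).

Sampling is affine-invariant ensemble MCMC (emcee) over the three
continuous parameters (log₁₀ K_d, log₁₀ a, σ); b is marginalized by exact
summation over its prior support at every likelihood evaluation, which
removes a poorly mixing discrete dimension.  For reporting, a b value is
drawn per posterior sample from its conditional distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .binding import BindingCurve, CalibrationCurve, EquilibriumParams, fraction_bound_linear
from .errors import ConfigurationError, InvalidInputError

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Prior choices for (log₁₀ K_d, log₁₀ a, b, σ).

    Bounds are inclusive and the densities flat on the stated scale.  The
    default b prior is a point mass at 1 (monomer); use
    :meth:`with_oligomer_b` or pass explicit weights for oligomers.
    """

    log10_kd_bounds: tuple[float, float] = (-12.0, -3.0)
    log10_a_bounds: tuple[float, float] = (-8.0, 0.0)
    b_weights: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    sigma_max: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi in (self.log10_kd_bounds, self.log10_a_bounds):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ConfigurationError("prior bounds must be finite and ordered")
        if self.sigma_max <= 0:
            raise ConfigurationError("sigma_max must be > 0")
        w = dict(self.b_weights)
        if not w or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ConfigurationError("b prior weights must be non-negative and sum > 0")
        if any(int(b) != b or b < 1 for b in w):
            raise ConfigurationError("b support must be integers >= 1")
        total = sum(w.values())
        object.__setattr__(self, "b_weights", {int(b): v / total for b, v in sorted(w.items())})

    @staticmethod
    def with_oligomer_b(b_min: int = 30, b_max: int = 40, **kwargs) -> "PriorSpec":
        """Uniform b prior over an oligomer subunit range (default 30–40)."""
        weights = {b: 1.0 for b in range(b_min, b_max + 1)}
        return PriorSpec(b_weights=weights, **kwargs)


@dataclass(frozen=True)
class SamplerConfig:
    n_walkers: int = 24
    n_steps: int = 1600
    n_burn: int = 600
    rhat_threshold: float = 1.05
    ess_threshold: float = 400.0


@dataclass
class Posterior:
    """Posterior draws with diagnostics and marginal summaries.

    ``draws`` has equally weighted rows with columns
    (log10_kd, log10_a, b, sigma); ``b_pmf`` is the marginal posterior mass
    function of the subunit count; ``diagnostics`` records split-chain R̂,
    bulk ESS, convergence and prior-boundary pileup flags.
    """

    draws: pd.DataFrame
    diagnostics: dict
    b_pmf: dict[int, float]
    priors: PriorSpec

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self)


def observed_fractions(
    curve: BindingCurve,
    conversion: str = "linear",
    calibration: CalibrationCurve | None = None,
) -> np.ndarray:
    """Convert a curve's apparent radii to bound fractions (clamped to [0,1])."""
    if conversion == "linear":
        return fraction_bound_linear(curve.apparent_radii, curve.r_free, curve.r_bound)
    if conversion == "calibrated":
        if calibration is None:
            raise ConfigurationError("calibrated conversion requires a CalibrationCurve")
        return calibration.fraction_bound(curve.apparent_radii)
    raise ConfigurationError(f"unknown conversion mode {conversion!r}")


def log_likelihood(
    curve: BindingCurve,
    params: EquilibriumParams,
    sigma: float,
    conversion: str = "linear",
    calibration: CalibrationCurve | None = None,
) -> float:
    """Gaussian log-likelihood of a binding curve under fixed parameters.

    Independent normal densities, mean the equilibrium bound fraction at
    each lipid concentration, common standard deviation ``sigma``.
    """
    if sigma <= 0:
        raise InvalidInputError("sigma must be > 0")
    fobs = observed_fractions(curve, conversion, calibration)
    fmod = _model_fractions(
        curve.lipid_totals, curve.protein_total,
        params.k_d, params.a, np.array([params.b]),
    )[0, :, 0]
    resid = fobs - fmod
    n = fobs.size
    return float(-0.5 * np.sum(resid**2) / sigma**2 - n * math.log(sigma) - 0.5 * n * LOG_2PI)


def _model_fractions(lipid, protein_total, kd, a, b_vals):
    """Equilibrium bound fraction with shape (walkers, points, b_support).

    ``kd`` and ``a`` may be scalars or 1-D arrays of per-walker values.
    """
    kd = np.atleast_1d(np.asarray(kd, dtype=float))[:, None, None]
    a = np.atleast_1d(np.asarray(a, dtype=float))[:, None, None]
    lipid = np.asarray(lipid, dtype=float)[None, :, None]
    b = np.asarray(b_vals, dtype=float)[None, None, :]
    p0 = protein_total / b
    s0 = a * lipid
    s = p0 + s0 + kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * p0 * s0, 0.0))
    ps = 2.0 * p0 * s0 / (s + disc)
    return np.clip(ps / p0, 0.0, 1.0)


class _PosteriorDensity:
    """Vectorized log-posterior over walkers, with b marginalized."""

    def __init__(self, fobs, lipid, protein_total, priors: PriorSpec):
        self.fobs = np.asarray(fobs, dtype=float)
        self.lipid = np.asarray(lipid, dtype=float)
        self.protein_total = float(protein_total)
        self.priors = priors
        self.b_vals = np.array(sorted(priors.b_weights), dtype=int)
        self.b_logw = np.log(np.array([priors.b_weights[b] for b in self.b_vals]))
        self.n = self.fobs.size

    def _in_bounds(self, theta):
        lkd, la, sig = theta[:, 0], theta[:, 1], theta[:, 2]
        p = self.priors
        return (
            (lkd >= p.log10_kd_bounds[0]) & (lkd <= p.log10_kd_bounds[1])
            & (la >= p.log10_a_bounds[0]) & (la <= p.log10_a_bounds[1])
            & (sig > 0) & (sig <= p.sigma_max)
        )

    def conditional_b_logweights(self, theta):
        """Per-walker log joint over the b support (points summed out)."""
        kd = 10.0 ** theta[:, 0]
        a = 10.0 ** theta[:, 1]
        sig = theta[:, 2][:, None]
        fmod = _model_fractions(self.lipid, self.protein_total, kd, a, self.b_vals)
        resid = self.fobs[None, :, None] - fmod  # (W, P, B)
        ssr = np.sum(resid * resid, axis=1)  # (W, B)
        loglik = -0.5 * ssr / sig**2 - self.n * np.log(sig) - 0.5 * self.n * LOG_2PI
        return loglik + self.b_logw[None, :]

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        ok = self._in_bounds(theta)
        out = np.full(theta.shape[0], -np.inf)
        if np.any(ok):
            lw = self.conditional_b_logweights(theta[ok])
            out[ok] = logsumexp(lw, axis=1)
        return out


def _initial_guess(density: _PosteriorDensity, priors: PriorSpec) -> np.ndarray:
    """Coarse grid search over (log K_d, log a) to seed the walkers."""
    lkd = np.linspace(*priors.log10_kd_bounds, 40)
    la = np.linspace(*priors.log10_a_bounds, 40)
    b_mid = int(np.median(density.b_vals))
    best, best_sse = (lkd[0], la[0]), np.inf
    for x in lkd:
        fmod = _model_fractions(
            density.lipid, density.protein_total, np.full_like(la, 10.0**x), 10.0**la,
            np.array([b_mid]),
        )[:, :, 0]  # (len(la), P)
        sse = np.sum((fmod - density.fobs[None, :]) ** 2, axis=1)
        j = int(np.argmin(sse))
        if sse[j] < best_sse:
            best_sse, best = float(sse[j]), (float(x), float(la[j]))
    sigma0 = max(math.sqrt(best_sse / density.n), 1e-3)
    return np.array([best[0], best[1], min(sigma0, priors.sigma_max * 0.5)])


def infer_posterior(
    curve: BindingCurve,
    priors: PriorSpec,
    seed: int,
    sampler_config: SamplerConfig | None = None,
    conversion: str = "linear",
    calibration: CalibrationCurve | None = None,
) -> Posterior:
    """Sample the posterior over (log₁₀ K_d, log₁₀ a, σ) with b marginalized.

    Deterministic given ``seed``.  Convergence is assessed by split-chain
    R̂ (< threshold) and bulk effective sample size; a non-converged run is
    still returned, flagged in ``diagnostics``.
    """
    cfg = sampler_config or SamplerConfig()
    fobs = observed_fractions(curve, conversion, calibration)
    density = _PosteriorDensity(fobs, curve.lipid_totals, curve.protein_total, priors)
    rng = np.random.default_rng(seed)

    center = _initial_guess(density, priors)
    ndim = 3
    p0 = center[None, :] + 1e-3 * rng.standard_normal((cfg.n_walkers, ndim))
    p0[:, 0] = np.clip(p0[:, 0], *priors.log10_kd_bounds)
    p0[:, 1] = np.clip(p0[:, 1], *priors.log10_a_bounds)
    p0[:, 2] = np.clip(p0[:, 2], 1e-4, priors.sigma_max)

    sampler = emcee.EnsembleSampler(cfg.n_walkers, ndim, density, vectorize=True)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, cfg.n_steps, progress=False)

    chain = sampler.get_chain(discard=cfg.n_burn)  # (steps, walkers, dim)
    names = ["log10_kd", "log10_a", "sigma"]
    idata = az.from_dict(
        posterior={k: chain[:, :, i].T for i, k in enumerate(names)}
    )
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in names}
    ess = {k: float(ess_ds[k].values) for k in names}
    converged = all(v < cfg.rhat_threshold for v in rhat.values()) and all(
        v > cfg.ess_threshold for v in ess.values()
    )

    flat = chain.reshape(-1, ndim)
    # Conditional draw of b per posterior sample (point mass short-circuits).
    if density.b_vals.size == 1:
        b_draws = np.full(flat.shape[0], density.b_vals[0])
        b_pmf = {int(density.b_vals[0]): 1.0}
    else:
        lw = density.conditional_b_logweights(flat)
        lw -= logsumexp(lw, axis=1, keepdims=True)
        w = np.exp(lw)
        cum = np.cumsum(w, axis=1)
        u = rng.random(flat.shape[0])[:, None]
        b_draws = density.b_vals[np.argmax(u < cum, axis=1)]
        b_pmf = {
            int(b): float(np.mean(w[:, j])) for j, b in enumerate(density.b_vals)
        }

    draws = pd.DataFrame(
        {
            "log10_kd": flat[:, 0],
            "log10_a": flat[:, 1],
            "b": b_draws,
            "sigma": flat[:, 2],
        }
    )
    boundary = {
        "log10_kd": _boundary_pileup(flat[:, 0], priors.log10_kd_bounds),
        "log10_a": _boundary_pileup(flat[:, 1], priors.log10_a_bounds),
    }
    diagnostics = {
        "rhat": rhat,
        "ess": ess,
        "converged": converged,
        "boundary_pileup": boundary,
        "n_draws": int(flat.shape[0]),
        "seed": int(seed),
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
    }
    return Posterior(draws=draws, diagnostics=diagnostics, b_pmf=b_pmf, priors=priors)


def _boundary_pileup(x: np.ndarray, bounds: tuple[float, float], frac: float = 0.02) -> bool:
    lo, hi = bounds
    edge = frac * (hi - lo)
    return bool(np.mean(x < lo + edge) > 0.1 or np.mean(x > hi - edge) > 0.1)


def summarize_posterior(post: Posterior) -> pd.DataFrame:
    """Marginal summaries: median and central 68%/95% intervals.

    K_d is reported in molar, the stoichiometry as lipids per binding site
    computed per draw as 1/a = 10^(−log₁₀ a) and then summarized (the
    reciprocal of a skewed posterior's summary is not the summary of the
    reciprocal).
    """
    if post.draws.empty:
        raise InvalidInputError("posterior has no draws")
    qs = [0.025, 0.16, 0.5, 0.84, 0.975]
    rows = {}
    rows["kd_molar"] = np.quantile(10.0 ** post.draws["log10_kd"], qs)
    rows["lipids_per_site"] = np.quantile(10.0 ** (-post.draws["log10_a"]), qs)
    rows["sigma"] = np.quantile(post.draws["sigma"], qs)
    rows["b"] = np.quantile(post.draws["b"], qs)
    out = pd.DataFrame(rows, index=["q2.5", "q16", "median", "q84", "q97.5"]).T
    out.index.name = "parameter"
    return out
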