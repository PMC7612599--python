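"""Prior, likelihood and posterior computation for the combination model.

The five model parameters are sampled on the unconstrained scale
``x = (alpha01, log alpha11, alpha02, log alpha12, eta)``: the intercepts
and log-slopes of each agent carry bivariate normal priors and the
interaction ``eta`` a normal prior, optionally truncated to nonnegative
(synergistic-or-additive) values.  Posterior draws are obtained with the
affine-invariant ensemble sampler (emcee); a deterministic quadrature
oracle over a 5-D grid provides an independent check of every posterior
functional on small datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import emcee
from scipy.stats import norm

from .models import ReferenceDoses, combination_risk

__all__ = [
    "PriorHyperparameters",
    "TrialData",
    "SamplerSettings",
    "PosteriorDraws",
    "log_prior",
    "log_likelihood",
    "sample_posterior",
    "prob_exceeds",
    "prob_in_interval",
    "posterior_mean_risk",
    "grid_posterior_oracle",
]


@dataclass(frozen=True)
class PriorHyperparameters:
    """Hyper-parameters of the calibrated prior.

    Intercepts and log-slopes carry bivariate normal priors per agent
    (methadone first): ``mu0`` are the intercept means, ``slope_median``
    the prior medians of the (log-normally distributed) slopes, ``sigma0``
    and ``sigma1`` the standard deviations of the intercepts and
    log-slopes, and ``sigma01`` the intercept/log-slope covariances.  The
    interaction prior is normal with scale ``sigma_eta``, truncated to
    nonnegative (synergistic-or-additive toxicity) when
    ``eta_nonnegative`` is set — the default, matching the design's
    working assumption that adding the escalated agent cannot reduce risk.
    """

    mu0: tuple[float, float] = (-3.75, -3.25)
    slope_median: tuple[float, float] = (0.40, 0.05)
    sigma0: tuple[float, float] = (0.50, 0.50)
    sigma1: tuple[float, float] = (0.35, 0.35)
    sigma01: tuple[float, float] = (0.0, 0.0)
    sigma_eta: float = 1.25
    eta_nonnegative: bool = True
    refs: ReferenceDoses = field(default_factory=ReferenceDoses)

    def __post_init__(self) -> None:
        if min(self.slope_median) <= 0:
            raise ValueError("slope medians must be strictly positive")
        for i in range(2):
            cov = self.covariance(i)
            if np.linalg.det(cov) <= 0 or cov[0, 0] <= 0:
                raise ValueError(f"agent-{i + 1} covariance is not positive definite")
        if self.sigma_eta <= 0:
            raise ValueError("sigma_eta must be strictly positive")

    def covariance(self, agent: int) -> np.ndarray:
        """2x2 prior covariance of (intercept, log-slope) for agent 0 or 1."""
        return np.array(
            [
                [self.sigma0[agent] ** 2, self.sigma01[agent]],
                [self.sigma01[agent], self.sigma1[agent] ** 2],
            ]
        )

    @property
    def log_slope_mean(self) -> tuple[float, float]:
        """Means of the log-slopes (log of the slope medians)."""
        return (float(np.log(self.slope_median[0])), float(np.log(self.slope_median[1])))

    @property
    def mean_vector(self) -> np.ndarray:
        """Prior mean on the unconstrained scale (eta mean is zero)."""
        l1, l2 = self.log_slope_mean
        return np.array([self.mu0[0], l1, self.mu0[1], l2, 0.0])


@dataclass(frozen=True)
class TrialData:
    """Accrued patient records: (methadone mg, baclofen mg, DLT indicator)."""

    records: tuple[tuple[float, float, int], ...] = ()

    def __post_init__(self) -> None:
        for m, b, y in self.records:
            if m < 0 or b < 0:
                raise ValueError("doses must be nonnegative")
            if y not in (0, 1):
                raise ValueError("DLT outcomes must be binary")

    @classmethod
    def from_records(cls, records) -> "TrialData":
        return cls(tuple((float(m), float(b), int(y)) for m, b, y in records))

    def extend(self, records) -> "TrialData":
        return TrialData.from_records(list(self.records) + list(records))

    def arrays(self):
        if not self.records:
            return (np.empty(0), np.empty(0), np.empty(0))
        m, b, y = map(np.asarray, zip(*self.records))
        return m.astype(float), b.astype(float), y.astype(float)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampler settings.

    Defaults give 40 walkers x 1100 retained steps = 44,000 dependent draws;
    with the chain's typical autocorrelation this leaves enough effective
    draws to keep the Monte-Carlo error of decision probabilities near 0.01.
    """

    n_walkers: int = 40
    n_steps: int = 1500
    n_burn: int = 400
    max_autocorr_warn: float = 80.0

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_steps:
            raise ValueError("burn-in must be shorter than the chain")
        if self.n_walkers < 12:
            raise ValueError("too few walkers for a 5-D ensemble")


#: lighter settings used inside large simulation studies: many walkers keep
#: the draw count up while fewer steps cap the per-update wall time
FAST_SETTINGS = SamplerSettings(n_walkers=64, n_steps=220, n_burn=100)


@dataclass(frozen=True)
class PosteriorDraws:
    """Flattened posterior draws on the natural scale.

    ``draws`` has columns (alpha01, alpha11, alpha02, alpha12, eta) with
    slopes already exponentiated; ``meta`` records sampler settings, the
    seed and convergence diagnostics.
    """

    draws: np.ndarray
    refs: ReferenceDoses
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[1] != 5 or not len(self.draws):
            raise ValueError("draws must be a nonempty (n, 5) array")

    def risk(self, m, b):
        """Vector of combination risks at (m, b), one per draw."""
        return combination_risk(self.draws, m, b, self.refs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.draws,
            columns=["alpha01", "alpha11", "alpha02", "alpha12", "eta"],
        )


def _unconstrained_mean_sd(hyper: PriorHyperparameters):
    mean = hyper.mean_vector
    sd = np.array(
        [
            hyper.sigma0[0],
            hyper.sigma1[0],
            hyper.sigma0[1],
            hyper.sigma1[1],
            hyper.sigma_eta,
        ]
    )
    return mean, sd


def log_prior(theta, hyper: PriorHyperparameters, *, slope_space: bool = True):
    """Log prior density of theta (natural scale by default).

    With ``slope_space=True`` the density includes the Jacobian of the log
    transform of the slopes; with ``False`` the argument is taken on the
    unconstrained scale (log-slopes), as used by the sampler.  Vectorised
    over a leading axis.
    """
    arr = np.asarray(theta, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    a01, s1, a02, s2, eta = arr.T
    if slope_space:
        bad = (s1 <= 0) | (s2 <= 0)
        l1 = np.log(np.where(s1 > 0, s1, 1.0))
        l2 = np.log(np.where(s2 > 0, s2, 1.0))
        jac = -l1 - l2  # d(log s)/ds = 1/s
    else:
        bad = np.zeros(len(arr), dtype=bool)
        l1, l2 = s1, s2
        jac = 0.0
    # two bivariate-normal blocks plus the (possibly truncated) eta term
    out = np.zeros(len(arr))
    for agent, (a, l) in enumerate(((a01, l1), (a02, l2))):
        cov = PriorHyperparameters.covariance(hyper, agent)
        prec = np.linalg.inv(cov)
        d0 = a - hyper.mu0[agent]
        d1 = l - hyper.log_slope_mean[agent]
        quad = prec[0, 0] * d0**2 + 2 * prec[0, 1] * d0 * d1 + prec[1, 1] * d1**2
        out += -0.5 * quad - 0.5 * np.log((2 * np.pi) ** 2 * np.linalg.det(cov))
    if hyper.eta_nonnegative:
        out += np.where(
            eta >= 0,
            norm.logpdf(eta, 0.0, hyper.sigma_eta) + np.log(2.0),
            -np.inf,
        )
    else:
        out += norm.logpdf(eta, 0.0, hyper.sigma_eta)
    out = np.where(bad, -np.inf, out + jac)
    return float(out[0]) if scalar else out


def log_likelihood(theta, data: TrialData, refs: ReferenceDoses = ReferenceDoses()):
    """Bernoulli log likelihood of the accrued records under theta."""
    if not len(data):
        arr = np.asarray(theta, dtype=float)
        return 0.0 if arr.ndim == 1 else np.zeros(arr.shape[:-1])
    m, b, y = data.arrays()
    arr = np.asarray(theta, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    p = combination_risk(arr[:, None, :], m[None, :], b[None, :], refs)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p), axis=-1)
    return float(ll[0]) if scalar else ll


def _make_log_posterior(hyper: PriorHyperparameters, m, b, y):
    """Factory for the vectorised log posterior on the sampler scale.

    Precomputes the prior precision matrices and the per-record dose
    transforms once; the returned closure is called tens of thousands of
    times per posterior update, so it stays lean.
    """
    prec = [np.linalg.inv(hyper.covariance(i)) for i in range(2)]
    mu = hyper.mean_vector
    refs = hyper.refs
    sigma_eta2 = hyper.sigma_eta**2
    trunc = hyper.eta_nonnegative
    has_data = len(m) > 0
    if has_data:
        log_m = np.log(m / refs.m_star)[None, :]
        with np.errstate(divide="ignore"):
            log_b = np.log(b / refs.b_star)[None, :]
        b_pos = (b > 0)[None, :]
        cov_eta = ((m / refs.m_star) * (b / refs.b_top))[None, :]
        y_row = y[None, :]

    def log_posterior(x):
        x = np.atleast_2d(x)
        a01, l1, a02, l2, eta = x.T
        d0 = a01 - mu[0]
        d1 = l1 - mu[1]
        lp = -0.5 * (
            prec[0][0, 0] * d0**2
            + 2 * prec[0][0, 1] * d0 * d1
            + prec[0][1, 1] * d1**2
        )
        d0 = a02 - mu[2]
        d1 = l2 - mu[3]
        lp -= 0.5 * (
            prec[1][0, 0] * d0**2
            + 2 * prec[1][0, 1] * d0 * d1
            + prec[1][1, 1] * d1**2
        )
        lp -= 0.5 * eta**2 / sigma_eta2
        if trunc:
            lp = np.where(eta < 0, -np.inf, lp)
        if has_data:
            logit_m = a01[:, None] + np.exp(l1)[:, None] * log_m
            logit_b = a02[:, None] + np.exp(l2)[:, None] * log_b
            p_m = 1.0 / (1.0 + np.exp(-np.clip(logit_m, -600, 600)))
            p_b = np.where(
                b_pos, 1.0 / (1.0 + np.exp(-np.clip(logit_b, -600, 600))), 0.0
            )
            p0 = np.clip(1.0 - (1.0 - p_m) * (1.0 - p_b), 1e-12, 1.0 - 1e-12)
            logit = np.log(p0) - np.log1p(-p0) + eta[:, None] * cov_eta
            p = np.clip(
                1.0 / (1.0 + np.exp(-np.clip(logit, -600, 600))),
                1e-12,
                1.0 - 1e-12,
            )
            lp = lp + np.sum(
                y_row * np.log(p) + (1.0 - y_row) * np.log1p(-p), axis=-1
            )
        return lp

    return log_posterior


def sample_posterior(
    hyper: PriorHyperparameters,
    data: TrialData,
    settings: SamplerSettings = SamplerSettings(),
    seed: int = 0,
) -> PosteriorDraws:
    """Draw from the posterior of theta given the accrued trial data.

    With empty data the draws reproduce the prior.  Convergence is
    monitored through the integrated autocorrelation time; an estimate
    exceeding ``settings.max_autocorr_warn`` steps triggers a warning and
    is recorded in ``meta`` rather than failing silently.
    """
    m, b, y = data.arrays()
    rng = np.random.default_rng(seed)
    mean, sd = _unconstrained_mean_sd(hyper)
    p0 = mean + 0.3 * sd * rng.standard_normal((settings.n_walkers, 5))
    if hyper.eta_nonnegative:
        p0[:, 4] = np.abs(p0[:, 4]) + 1e-3
    sampler = emcee.EnsembleSampler(
        settings.n_walkers,
        5,
        _make_log_posterior(hyper, m, b, y),
        vectorize=True,
    )
    # the setter expects a state tuple; anything else is silently ignored
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, settings.n_steps, progress=False)
    chain = sampler.get_chain(discard=settings.n_burn, flat=True)
    draws = np.stack(
        [
            chain[:, 0],
            np.exp(chain[:, 1]),
            chain[:, 2],
            np.exp(chain[:, 3]),
            chain[:, 4],
        ],
        axis=-1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            tau = float(
                np.nanmax(
                    sampler.get_autocorr_time(discard=settings.n_burn, tol=0)
                )
            )
        except Exception:  # pragma: no cover - diagnostic only
            tau = float("nan")
    meta = {
        "seed": seed,
        "n_walkers": settings.n_walkers,
        "n_steps": settings.n_steps,
        "n_burn": settings.n_burn,
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "max_autocorr_time": tau,
        "converged": not (np.isfinite(tau) and tau > settings.max_autocorr_warn),
    }
    if not meta["converged"]:
        warnings.warn(
            f"posterior chain mixing is slow (tau={tau:.0f} steps); "
            "functional estimates may be noisy",
            RuntimeWarning,
        )
    return PosteriorDraws(draws=draws, refs=hyper.refs, meta=meta)


def prob_exceeds(draws: PosteriorDraws, m, b, threshold: float) -> float:
    """Posterior probability that the risk at (m, b) exceeds ``threshold``."""
    return float(np.mean(draws.risk(m, b) > threshold))


def prob_in_interval(draws: PosteriorDraws, m, b, lo: float, hi: float) -> float:
    """Posterior probability that the risk at (m, b) lies in (lo, hi)."""
    if not lo < hi:
        raise ValueError("interval bounds must satisfy lo < hi")
    r = draws.risk(m, b)
    return float(np.mean((r > lo) & (r < hi)))


def posterior_mean_risk(draws: PosteriorDraws, m, b) -> float:
    return float(np.mean(draws.risk(m, b)))


class GridOracle:
    """Deterministic quadrature over a 5-D parameter grid.

    Intended as an independent cross-check of the sampler on small datasets:
    posterior weights are prior densities times the Bernoulli likelihood on
    a tensor grid spanning ``span`` prior standard deviations per axis, and
    every functional is a weighted sum.  Infeasible beyond ~15 nodes/axis.
    """

    def __init__(
        self,
        hyper: PriorHyperparameters,
        data: TrialData,
        n_nodes: int = 13,
        span: float = 4.0,
    ):
        if n_nodes > 15:
            raise ValueError("grid too large to enumerate")
        self.hyper = hyper
        self.refs = hyper.refs
        self._data = data
        mean, sd = _unconstrained_mean_sd(hyper)
        # pass 1: grid spanning the prior; pass 2: recentred on the
        # posterior moments found in pass 1 (the likelihood shrinks the
        # posterior well below the prior's scale once data accrue).
        x, w = self._weighted_grid(mean, sd, n_nodes, span)
        if len(data):
            post_mean = w @ x
            post_sd = np.sqrt(np.maximum(w @ x**2 - post_mean**2, 1e-12))
            x, w = self._weighted_grid(post_mean, 5.0 * post_sd, n_nodes, 1.0)
        self.theta = np.stack(
            [x[:, 0], np.exp(x[:, 1]), x[:, 2], np.exp(x[:, 3]), x[:, 4]], axis=-1
        )
        self.weights = w

    def _weighted_grid(self, centre, scale, n_nodes, span):
        """Tensor grid of unconstrained nodes with normalised posterior weights."""
        prior_mean, prior_sd = _unconstrained_mean_sd(self.hyper)
        axes = []
        for i in range(5):
            lo, hi = centre[i] - span * scale[i], centre[i] + span * scale[i]
            if i == 4 and self.hyper.eta_nonnegative:
                lo = max(lo, 0.0)
            axes.append(np.linspace(lo, hi, n_nodes))
        mesh = np.meshgrid(*axes, indexing="ij")
        x = np.stack([g.ravel() for g in mesh], axis=1)
        # prior density on the unconstrained scale (uniform node spacing per
        # axis, so spacing constants cancel on normalisation; trapezoid
        # endpoint halving removes boundary double-counting)
        logw = np.zeros(x.shape[0])
        wts = []
        for i in range(5):
            w_i = norm.pdf((axes[i] - prior_mean[i]) / prior_sd[i])
            w_i[0] *= 0.5
            w_i[-1] *= 0.5
            wts.append(np.log(np.maximum(w_i, 1e-300)))
        for i, g in enumerate(np.meshgrid(*wts, indexing="ij")):
            logw += g.ravel()
        if self.hyper.eta_nonnegative:
            logw[x[:, 4] < 0] = -np.inf
        if len(self._data):
            m, b, y = self._data.arrays()
            theta = np.stack(
                [x[:, 0], np.exp(x[:, 1]), x[:, 2], np.exp(x[:, 3]), x[:, 4]],
                axis=-1,
            )
            p = combination_risk(theta[:, None, :], m[None, :], b[None, :], self.refs)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            logw = logw + np.sum(y * np.log(p) + (1 - y) * np.log1p(-p), axis=-1)
        logw -= logw.max()
        w = np.exp(logw)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise FloatingPointError(
                "all quadrature weights underflowed; recentre the grid"
            )
        return x, w / total

    def _risk(self, m, b):
        return combination_risk(self.theta, m, b, self.refs)

    def prob_exceeds(self, m, b, threshold: float) -> float:
        return float(np.sum(self.weights * (self._risk(m, b) > threshold)))

    def prob_in_interval(self, m, b, lo: float, hi: float) -> float:
        r = self._risk(m, b)
        return float(np.sum(self.weights * ((r > lo) & (r < hi))))

    def mean_risk(self, m, b) -> float:
        return float(np.sum(self.weights * self._risk(m, b)))


def grid_posterior_oracle(
    hyper: PriorHyperparameters,
    data: TrialData,
    n_nodes: int = 13,
    span: float = 4.0,
) -> GridOracle:
    """Build the deterministic quadrature oracle (see :class:`GridOracle`)."""
    return GridOracle(hyper, data, n_nodes=n_nodes, span=span)
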