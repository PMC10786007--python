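"""Hierarchical Bayesian reliability models for naming latencies and accuracy.

Reliability of participants' mean naming speed is estimated as the
correlation of by-participant random effects in a bivariate hierarchical
model of log-latencies. For a chosen split of the correct trials into two
halves (even/odd, first/second, session, or task condition), the model is

    log latency ~ Normal(mu[half] + b[participant, half] + g[item], sigma)
    (b[p, 1], b[p, 2]) ~ MVN(0, diag(tau) * R * diag(tau)),   R = [[1, rho], [rho, 1]]
    g[i] ~ Normal(0, sigma_item)

with no global intercept: each half gets its own intercept and its own
by-participant adjustment, so rho is the split-half (or test-retest /
cross-condition) reliability, free of trial- and item-level noise that
attenuates a Pearson correlation of raw participant means.

Priors follow the regularizing choices standard for naming latencies:
intercepts Normal(6.75, 1.5) on the log scale (prior median ~854 ms),
half-Normal(0, 1) on all SDs, and LKJ(eta=2) on the random-effect
correlation.

Because all latent effects are Gaussian, they are marginalized analytically
(Woodbury identity on the crossed random-effects covariance), leaving a
7-dimensional hyperparameter posterior sampled by affine-invariant ensemble
MCMC (emcee). The companion accuracy model (binomial link, by-participant
intercepts per condition) marginalizes its participant effects with 2-D
Gauss-Hermite quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .posterior import PosteriorSummary

__all__ = [
    "SplitSpec",
    "ModelSpec",
    "AccuracyPriors",
    "assign_split",
    "fit_reliability",
    "fit_accuracy",
    "extract_participant_effects",
    "ReliabilityFit",
    "AccuracyFit",
]

SCHEMES = ("even_odd", "first_second", "session", "condition")


@dataclass(frozen=True)
class SplitSpec:
    """How to divide analyzed trials into the two correlated halves.

    ``even_odd`` and ``first_second`` split by the original 1-based
    presentation index (excluded trials do not renumber the remainder);
    ``session`` and ``condition`` use those columns directly.
    """

    scheme: str = "even_odd"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown split scheme {self.scheme!r}; one of {SCHEMES}")


@dataclass(frozen=True)
class ModelSpec:
    """Priors and sampler settings for the latency reliability model.

    Prior defaults are the regularizing choices described in the module
    docstring and should normally be left alone. Sampler settings trade
    accuracy for wall time; :meth:`reduced` is a desk-scale preset for test
    suites and quick exploration.
    """

    prior_intercept_mean: float = 6.75
    prior_intercept_sd: float = 1.5
    prior_sd_scale: float = 1.0
    lkj_eta: float = 2.0
    n_walkers: int = 32
    n_warmup: int = 500
    n_steps: int = 1000
    seed: int = 1234

    @classmethod
    def reduced(cls, seed: int = 1234) -> "ModelSpec":
        return cls(n_walkers=16, n_warmup=300, n_steps=400, seed=seed)


@dataclass(frozen=True)
class AccuracyPriors:
    """Priors and sampler settings for the binomial accuracy model."""

    prior_intercept_mean: float = 0.0
    prior_intercept_sd: float = 1.5
    prior_sd_scale: float = 1.0
    lkj_eta: float = 2.0
    n_quad: int = 16
    n_walkers: int = 16
    n_warmup: int = 300
    n_steps: int = 600
    seed: int = 1234


def assign_split(trials: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Label every trial with one of two half labels under the split scheme.

    Returns a copy with a ``half`` column. For index-based schemes the
    parity / midpoint is computed on the original presentation index
    (``trial_index``), so prior exclusions do not shift labels.
    """
    out = trials.copy()
    if spec.scheme == "even_odd":
        out["half"] = np.where(out["trial_index"] % 2 == 0, "even", "odd")
    elif spec.scheme == "first_second":
        midpoint = out["trial_index"].max() / 2
        out["half"] = np.where(out["trial_index"] <= midpoint, "first", "second")
    elif spec.scheme == "session":
        levels = sorted(out["session"].unique())
        if len(levels) != 2:
            raise ValueError(f"session split needs exactly 2 sessions, found {levels}")
        out["half"] = out["session"].map({levels[0]: f"session{levels[0]}",
                                          levels[1]: f"session{levels[1]}"})
    else:  # condition
        levels = sorted(out["condition"].unique())
        if len(levels) != 2:
            raise ValueError(
                f"condition split needs exactly 2 conditions, found {levels}"
            )
        out["half"] = out["condition"]
    return out


# ---------------------------------------------------------------------------
# marginalized Gaussian likelihood for the latency model


class _MarginalRTModel:
    """Sufficient statistics and marginal log-likelihood of the RT model.

    Latent participant and item effects u = (b, g) enter as y = X mu + U u + eps.
    With D = Cov(u), the marginal covariance V = sigma^2 I + U D U' yields

        log|V| = N log sigma^2 + log|D| + log|M|,   M = D^{-1} + U'U / sigma^2
        r' V^{-1} r = (r'r - (U'r)' M^{-1} (U'r) / sigma^2) / sigma^2

    so each likelihood evaluation costs one Cholesky of the (2P+I) x (2P+I)
    capacitance matrix M; U'U, U'X, U'y etc. are precomputed once.
    """

    def __init__(self, y, p_idx, h_idx, i_idx, spec: ModelSpec):
        y = np.asarray(y, dtype=float)
        self.N = len(y)
        self.P = int(p_idx.max()) + 1
        self.I = int(i_idx.max()) + 1
        self.q = 2 * self.P + self.I
        self.spec = spec

        rows = np.arange(self.N)
        cols_b = 2 * p_idx + h_idx
        cols_g = 2 * self.P + i_idx
        data = np.ones(self.N)
        U = sparse.csr_matrix(
            (
                np.concatenate([data, data]),
                (np.concatenate([rows, rows]), np.concatenate([cols_b, cols_g])),
            ),
            shape=(self.N, self.q),
        )
        X = np.zeros((self.N, 2))
        X[rows, h_idx] = 1.0

        self.UtU = np.asarray((U.T @ U).todense())
        self.UtX = np.asarray(U.T @ X)
        self.Uty = np.asarray(U.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

        # moment-based starting point
        df = pd.DataFrame({"y": y, "p": p_idx, "h": h_idx})
        cell = df.groupby(["p", "h"])["y"].mean().unstack()
        self.cell_means = cell
        mu0 = cell.mean(axis=0).to_numpy()
        tau0 = np.clip(cell.std(axis=0).to_numpy(), 0.02, None)
        if cell.shape[1] == 2 and cell.notna().all().all():
            r0 = float(np.corrcoef(cell.iloc[:, 0], cell.iloc[:, 1])[0, 1])
        else:
            r0 = 0.0
        r0 = float(np.clip(np.nan_to_num(r0), -0.995, 0.995))
        resid = df["y"] - df.groupby("p")["y"].transform("mean")
        sig0 = max(float(resid.std()), 0.02)
        self.theta0 = np.array(
            [
                mu0[0],
                mu0[1],
                math.log(tau0[0]),
                math.log(tau0[1]),
                math.atanh(r0),
                math.log(max(0.5 * sig0, 0.02)),
                math.log(sig0),
            ]
        )

        self._diag_idx = np.arange(self.q)
        self._b_even = np.arange(0, 2 * self.P, 2)
        self._b_odd = self._b_even + 1

    def unpack(self, theta):
        mu = theta[:2]
        tau = np.exp(np.clip(theta[2:4], -12.0, 4.0))
        rho = math.tanh(float(np.clip(theta[4], -12.0, 12.0)))
        sig_g = math.exp(float(np.clip(theta[5], -12.0, 4.0)))
        sig_e = math.exp(float(np.clip(theta[6], -12.0, 4.0)))
        return mu, tau, rho, sig_g, sig_e

    def _capacitance(self, tau, rho, sig_g, sig_e):
        """M = D^{-1} + U'U/sigma^2 and log|D|."""
        det_b = tau[0] ** 2 * tau[1] ** 2 * (1.0 - rho**2)
        inv00 = tau[1] ** 2 / det_b
        inv11 = tau[0] ** 2 / det_b
        inv01 = -rho * tau[0] * tau[1] / det_b
        M = self.UtU / sig_e**2
        M[self._b_even, self._b_even] += inv00
        M[self._b_odd, self._b_odd] += inv11
        M[self._b_even, self._b_odd] += inv01
        M[self._b_odd, self._b_even] += inv01
        gi = self._diag_idx[2 * self.P :]
        M[gi, gi] += 1.0 / sig_g**2
        logdet_D = self.P * math.log(det_b) + self.I * 2 * math.log(sig_g)
        return M, logdet_D

    def loglik(self, theta) -> float:
        mu, tau, rho, sig_g, sig_e = self.unpack(theta)
        if min(tau) < 1e-5 or sig_g < 1e-5 or sig_e < 1e-5 or abs(rho) > 1 - 1e-10:
            return -np.inf
        M, logdet_D = self._capacitance(tau, rho, sig_g, sig_e)
        try:
            cf = cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_M = 2.0 * np.sum(np.log(np.diag(cf[0])))
        rr = self.yty - 2.0 * mu @ self.Xty + mu @ self.XtX @ mu
        Utr = self.Uty - self.UtX @ mu
        w = cho_solve(cf, Utr, check_finite=False)
        quad = (rr - Utr @ w / sig_e**2) / sig_e**2
        logdet_V = self.N * 2 * math.log(sig_e) + logdet_D + logdet_M
        return -0.5 * (self.N * math.log(2 * math.pi) + logdet_V + quad)

    def logprior(self, theta) -> float:
        spec = self.spec
        mu = theta[:2]
        log_tau = np.clip(theta[2:4], -12.0, 4.0)
        z = float(np.clip(theta[4], -12.0, 12.0))
        log_sg = float(np.clip(theta[5], -12.0, 4.0))
        log_se = float(np.clip(theta[6], -12.0, 4.0))
        tau = np.exp(log_tau)
        sig_g, sig_e = math.exp(log_sg), math.exp(log_se)
        rho = math.tanh(z)
        lp = -0.5 * np.sum(
            ((mu - spec.prior_intercept_mean) / spec.prior_intercept_sd) ** 2
        )
        # half-normal on SDs, with log-scale Jacobians
        s2 = spec.prior_sd_scale**2
        lp += -0.5 * (tau[0] ** 2 + tau[1] ** 2 + sig_g**2 + sig_e**2) / s2
        lp += log_tau[0] + log_tau[1] + log_sg + log_se
        # LKJ(eta) on the 2x2 correlation plus atanh Jacobian
        lp += (spec.lkj_eta - 1.0) * math.log1p(-rho * rho)
        lp += math.log1p(-rho * rho)
        return float(lp)

    def logpost(self, theta) -> float:
        lp = self.logprior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.loglik(theta)
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    def conditional_effect_means(self, theta) -> np.ndarray:
        """E[(b, g) | y, theta]: posterior mean of the latent effects."""
        mu, tau, rho, sig_g, sig_e = self.unpack(theta)
        M, _ = self._capacitance(tau, rho, sig_g, sig_e)
        cf = cho_factor(M, lower=True, check_finite=False)
        Utr = self.Uty - self.UtX @ mu
        return cho_solve(cf, Utr, check_finite=False) / sig_e**2


def _run_emcee(logpost, theta0, n_walkers, n_warmup, n_steps, seed, jitter=0.05):
    ndim = len(theta0)
    rng = np.random.default_rng(seed)
    p0 = theta0[None, :] + jitter * rng.standard_normal((n_walkers, ndim))
    # differential-evolution moves mix much better than the default stretch
    # move on these smooth, mildly correlated hyperposteriors
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, logpost, moves=moves)
    sampler.random_state = np.random.RandomState(seed).get_state()
    state = sampler.run_mcmc(p0, max(n_warmup // 2, 1), progress=False)
    # rescue walkers stranded far below the bulk (near-degenerate posteriors,
    # e.g. residual SD ~ 0, are razor-thin and can trap part of the ensemble)
    lp = state.log_prob
    stuck = lp < lp.max() - 25.0 * ndim
    if stuck.any():
        coords = state.coords.copy()
        coords[stuck] = state.coords[lp.argmax()] + 0.01 * rng.standard_normal(
            (int(stuck.sum()), ndim)
        )
        state = coords
    sampler.reset()
    state = sampler.run_mcmc(state, n_warmup - n_warmup // 2, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False)
    return sampler.get_chain()  # (n_steps, n_walkers, ndim)


def _diagnose(chain_2d: np.ndarray, rhat_threshold=1.01, ess_threshold=400.0) -> dict:
    """R-hat / ESS on a (draws, chains) array, walkers treated as chains."""
    arr = chain_2d.T[:, :]  # (chains, draws)
    rhat = float(az.rhat(arr))
    ess = float(az.ess(arr))
    return {
        "rhat": rhat,
        "ess": ess,
        "converged": bool(rhat <= rhat_threshold and ess >= ess_threshold),
        "rhat_threshold": rhat_threshold,
        "ess_threshold": ess_threshold,
    }


@dataclass
class ReliabilityFit:
    """Fitted latency reliability model: rho summary plus full hyperposterior."""

    summary: PosteriorSummary
    draws: dict
    participants: list
    items: list
    halves: tuple[str, str]
    spec: SplitSpec
    model: ModelSpec
    _marginal: _MarginalRTModel = field(repr=False, default=None)
    _chain: np.ndarray = field(repr=False, default=None)

    def participant_effects(self, half: str, n_draws: int = 100) -> pd.Series:
        """Posterior-mean by-participant speed effects for one half (log-ms).

        Rao-Blackwellized: the Gaussian conditional mean of the latent
        effects is averaged over a thinned subset of hyperparameter draws.
        """
        if half not in self.halves:
            raise ValueError(f"unknown half {half!r}; fitted halves are {self.halves}")
        h = self.halves.index(half)
        flat = self._chain.reshape(-1, self._chain.shape[-1])
        take = np.linspace(0, len(flat) - 1, min(n_draws, len(flat))).astype(int)
        acc = np.zeros(self._marginal.P)
        for t in take:
            u = self._marginal.conditional_effect_means(flat[t])
            acc += u[2 * np.arange(self._marginal.P) + h]
        acc /= len(take)
        return pd.Series(acc, index=self.participants, name=f"speed_{half}")


def fit_reliability(
    trials: pd.DataFrame, spec: SplitSpec, model: ModelSpec | None = None
) -> ReliabilityFit:
    """Fit the bivariate hierarchical latency model and summarize rho.

    ``trials`` must already be filtered to correct responses and, for the
    within-session schemes, subset to a single session/condition. Both
    halves must be populated for every participant.
    """
    model = model or ModelSpec()
    labelled = trials if "half" in trials.columns else assign_split(trials, spec)
    labelled = labelled.dropna(subset=["latency_ms"])
    if labelled["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if labelled["item_id"].nunique() < 2:
        raise ValueError("need at least 2 items")
    halves = tuple(sorted(labelled["half"].unique()))
    if len(halves) != 2:
        raise ValueError(f"expected exactly 2 half labels, found {halves}")
    per = labelled.groupby(["participant_id", "half"]).size().unstack()
    if per.isna().any().any() or (per == 0).any().any():
        empty = per.index[per.isna().any(axis=1) | (per == 0).any(axis=1)].tolist()
        raise ValueError(f"participants with an empty half: {empty[:5]}")

    participants = sorted(labelled["participant_id"].unique())
    items = sorted(labelled["item_id"].unique())
    p_idx = labelled["participant_id"].map({p: i for i, p in enumerate(participants)})
    i_idx = labelled["item_id"].map({it: i for i, it in enumerate(items)})
    h_idx = labelled["half"].map({halves[0]: 0, halves[1]: 1})
    y = np.log(labelled["latency_ms"].to_numpy(dtype=float))

    marg = _MarginalRTModel(
        y, p_idx.to_numpy(), h_idx.to_numpy(), i_idx.to_numpy(), model
    )
    chain = _run_emcee(
        marg.logpost, marg.theta0, model.n_walkers, model.n_warmup, model.n_steps,
        model.seed,
    )
    rho_chain = np.tanh(chain[:, :, 4])  # (draws, walkers)
    diagnostics = _diagnose(rho_chain)
    summary = PosteriorSummary.from_draws(rho_chain.ravel(), diagnostics)

    names = ["mu_1", "mu_2", "log_tau_1", "log_tau_2", "atanh_rho",
             "log_sigma_item", "log_sigma"]
    draws = {n: chain[:, :, k].ravel() for k, n in enumerate(names)}
    draws["rho"] = rho_chain.ravel()
    return ReliabilityFit(
        summary=summary,
        draws=draws,
        participants=participants,
        items=items,
        halves=halves,
        spec=spec,
        model=model,
        _marginal=marg,
        _chain=chain,
    )


# ---------------------------------------------------------------------------
# binomial accuracy model


class _MarginalAccuracyModel:
    """Binomial-link accuracy model with participant effects integrated out.

    Per participant p and condition/half c: k_pc correct of m_pc trials with
    P(correct) = logistic(alpha_c + a_pc), (a_p1, a_p2) ~ MVN(0, Sigma_a).
    The per-participant 2-D integral is evaluated by Gauss-Hermite
    quadrature, rotated through the Cholesky factor of Sigma_a.
    """

    def __init__(self, k: np.ndarray, m: np.ndarray, priors: AccuracyPriors):
        self.k = k  # (P, 2)
        self.m = m
        self.priors = priors
        nodes, weights = np.polynomial.hermite_e.hermegauss(priors.n_quad)
        z1, z2 = np.meshgrid(nodes, nodes, indexing="ij")
        self.z = np.stack([z1.ravel(), z2.ravel()], axis=1)  # (G, 2)
        w = np.outer(weights, weights).ravel()
        self.logw = np.log(w) - 2 * 0.5 * math.log(2 * math.pi)
        # normalize probabilists' Hermite weights to a proper N(0, I) average
        self.logw -= logsumexp(self.logw)
        self.theta0 = self._moment_start()

    def _moment_start(self):
        phat = np.clip((self.k + 0.5) / (self.m + 1.0), 1e-3, 1 - 1e-3)
        logit = np.log(phat / (1 - phat))
        alpha = logit.mean(axis=0)
        sd = np.clip(logit.std(axis=0), 0.1, None)
        r0 = float(np.clip(np.nan_to_num(np.corrcoef(logit[:, 0], logit[:, 1])[0, 1]),
                           -0.9, 0.9))
        return np.array([alpha[0], alpha[1], math.log(sd[0]), math.log(sd[1]),
                         math.atanh(r0)])

    def unpack(self, theta):
        alpha = theta[:2]
        sd = np.exp(np.clip(theta[2:4], -8.0, 3.0))
        rho = math.tanh(float(np.clip(theta[4], -12.0, 12.0)))
        return alpha, sd, rho

    def _participant_loglik(self, theta) -> np.ndarray:
        """(G, P) log-likelihood on the quadrature grid."""
        alpha, sd, rho = self.unpack(theta)
        L = np.array([[sd[0], 0.0], [sd[1] * rho, sd[1] * math.sqrt(1 - rho**2)]])
        a = self.z @ L.T  # (G, 2)
        logits = alpha[None, None, :] + a[:, None, :]  # (G, P(broadcast), 2)
        logp = -np.logaddexp(0.0, -logits)
        log1mp = -np.logaddexp(0.0, logits)
        ll = self.k[None] * logp + (self.m - self.k)[None] * log1mp  # (G, P, 2)
        return ll.sum(axis=2)

    def loglik(self, theta) -> float:
        ll = self._participant_loglik(theta)
        return float(logsumexp(ll + self.logw[:, None], axis=0).sum())

    def logprior(self, theta) -> float:
        pr = self.priors
        alpha = theta[:2]
        log_sd = np.clip(theta[2:4], -8.0, 3.0)
        z = float(np.clip(theta[4], -12.0, 12.0))
        sd = np.exp(log_sd)
        rho = math.tanh(z)
        lp = -0.5 * np.sum(((alpha - pr.prior_intercept_mean) / pr.prior_intercept_sd) ** 2)
        lp += -0.5 * np.sum(sd**2) / pr.prior_sd_scale**2 + np.sum(log_sd)
        lp += (pr.lkj_eta - 1.0) * math.log1p(-rho * rho) + math.log1p(-rho * rho)
        return float(lp)

    def logpost(self, theta) -> float:
        lp = self.logprior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglik(theta)

    def conditional_effect_means(self, theta) -> np.ndarray:
        """E[a_pc | data, theta] via the same quadrature grid: (P, 2)."""
        alpha, sd, rho = self.unpack(theta)
        L = np.array([[sd[0], 0.0], [sd[1] * rho, sd[1] * math.sqrt(1 - rho**2)]])
        a = self.z @ L.T
        ll = self._participant_loglik(theta) + self.logw[:, None]  # (G, P)
        w = np.exp(ll - logsumexp(ll, axis=0, keepdims=True))
        return w.T @ a  # (P, 2)


@dataclass
class AccuracyFit:
    """Fitted hierarchical accuracy model."""

    summaries: dict  # parameter name -> PosteriorSummary
    participants: list
    halves: tuple[str, str]
    _marginal: _MarginalAccuracyModel = field(repr=False, default=None)
    _chain: np.ndarray = field(repr=False, default=None)

    def participant_effects(self, half: str, n_draws: int = 100) -> pd.Series:
        if half not in self.halves:
            raise ValueError(f"unknown half {half!r}; fitted halves are {self.halves}")
        h = self.halves.index(half)
        flat = self._chain.reshape(-1, self._chain.shape[-1])
        take = np.linspace(0, len(flat) - 1, min(n_draws, len(flat))).astype(int)
        acc = np.zeros(len(self.participants))
        for t in take:
            acc += self._marginal.conditional_effect_means(flat[t])[:, h]
        acc /= len(take)
        return pd.Series(acc, index=self.participants, name=f"accuracy_{half}")


def fit_accuracy(
    trials: pd.DataFrame,
    spec: SplitSpec,
    priors: AccuracyPriors | None = None,
) -> AccuracyFit:
    """Fit the binomial-link hierarchical accuracy model.

    ``trials`` must be the *unfiltered* table (error trials carry the
    information); accuracy is response_class == "correct". Participants at
    100% are handled by partial pooling (no separation failure).
    """
    priors = priors or AccuracyPriors()
    labelled = trials if "half" in trials.columns else assign_split(trials, spec)
    halves = tuple(sorted(labelled["half"].unique()))
    if len(halves) != 2:
        raise ValueError(f"expected exactly 2 half labels, found {halves}")
    participants = sorted(labelled["participant_id"].unique())
    tab = (
        labelled.assign(correct=labelled["response_class"].eq("correct"))
        .groupby(["participant_id", "half"])["correct"]
        .agg(["sum", "count"])
    )
    k = tab["sum"].unstack().reindex(index=participants, columns=list(halves))
    m = tab["count"].unstack().reindex(index=participants, columns=list(halves))
    if m.isna().any().any():
        raise ValueError("every participant needs trials in both halves")

    marg = _MarginalAccuracyModel(
        k.to_numpy(dtype=float), m.to_numpy(dtype=float), priors
    )
    chain = _run_emcee(
        marg.logpost, marg.theta0, priors.n_walkers, priors.n_warmup, priors.n_steps,
        priors.seed,
    )
    names = ["alpha_1", "alpha_2", "log_sd_1", "log_sd_2", "atanh_rho"]
    summaries = {}
    for j, name in enumerate(names):
        vals = chain[:, :, j]
        if name.startswith("log_"):
            vals, name = np.exp(vals), name[4:]
        elif name == "atanh_rho":
            vals, name = np.tanh(vals), "rho"
        summaries[name] = PosteriorSummary.from_draws(vals.ravel(), _diagnose(vals))
    return AccuracyFit(
        summaries=summaries,
        participants=participants,
        halves=halves,
        _marginal=marg,
        _chain=chain,
    )


def extract_participant_effects(
    fit: ReliabilityFit | AccuracyFit, which: str, condition: str
) -> pd.Series:
    """Per-participant posterior-mean effects, ordered by participant_id.

    ``which`` is "speed" (a :class:`ReliabilityFit`) or "accuracy" (an
    :class:`AccuracyFit`); ``condition`` is one of the fitted half labels.
    """
    if which == "speed":
        if not isinstance(fit, ReliabilityFit):
            raise TypeError("speed effects require a ReliabilityFit")
    elif which == "accuracy":
        if not isinstance(fit, AccuracyFit):
            raise TypeError("accuracy effects require an AccuracyFit")
    else:
        raise ValueError(f"unknown effect kind {which!r}")
    return fit.participant_effects(condition)
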