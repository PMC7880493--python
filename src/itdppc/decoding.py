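"""Linear (lPPC) decoding of the log-posterior from population activity.

The decoder is a multinomial logistic regression whose classes are the K
delay-grid values and whose training targets are, on each trial, the *full*
posterior distribution computed by the ideal observer (probabilistic
targets), not a one-hot label. The objective is the mean KL divergence
between the true and the reconstructed posterior,

    L(W, b) = mean_t KL( p_t || softmax(W r_t + b) ),

minimized full-batch with L-BFGS and no regularization. If the population
is an lPPC of the observer, the minimum is zero in the infinite-data limit.

Reconstruction quality is summarized as percent information loss,
``100 * mean KL(true || decoded) / mean KL(true || prior)``, on held-out
trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, xlogy

from .ideal_observer import DelayGrid, Posterior
from .neural import PopulationResponse


def _as_rates(responses) -> np.ndarray:
    if isinstance(responses, PopulationResponse):
        return responses.rates
    return np.asarray(responses)


def make_dirac_targets(labels: np.ndarray, grid: DelayGrid) -> np.ndarray:
    """One-hot target distributions from true-delay labels (traditional
    multiclass training mode)."""
    idx = np.argmin(
        np.abs(np.asarray(labels)[:, None] - grid.delta_us[None, :]), axis=1
    )
    p = np.zeros((len(idx), grid.n))
    p[np.arange(len(idx)), idx] = 1.0
    return p


class PosteriorDecoder:
    """Multinomial logistic decoder with probabilistic targets.

    Parameters
    ----------
    responses : PopulationResponse or array (n_trials, n_units)
        Training population activity.
    targets : array (n_trials, K)
        Target distributions over the delay grid — either the true
        posteriors (probabilistic training, the default use) or one-hot
        labels from :func:`make_dirac_targets`.
    grid : DelayGrid
        Shared delay grid (decoder classes).
    """

    def __init__(self, responses, targets: np.ndarray, grid: DelayGrid):
        x = _as_rates(responses)
        p = np.asarray(targets, dtype=float)
        if x.ndim != 2 or p.ndim != 2:
            raise ValueError("responses and targets must be 2-D")
        if len(x) != len(p):
            raise ValueError("trial-count mismatch")
        if p.shape[1] != grid.n:
            raise ValueError("class-count mismatch with the delay grid")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite responses")
        self.x = np.asarray(x, dtype=float)
        self.targets = p
        self.grid = grid

    def fit(
        self, gtol: float = 1e-6, maxiter: int = 1500
    ) -> "PosteriorDecoderResults":
        """Full-batch L-BFGS minimization of the mean KL objective.

        Features are internally standardized (an invertible linear
        reparametrization, folded back into the returned weights) and one
        class column is pinned to zero to remove the softmax shift
        degeneracy; no regularization is applied.
        """
        x, p = self.x, self.targets
        n, u = x.shape
        k = self.grid.n
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd < 1e-12] = 1.0
        xs = np.column_stack([(x - mu) / sd, np.ones(n)])
        neg_entropy = float(np.sum(xlogy(p, p)) / n)

        def objective(theta):
            w = theta.reshape(u + 1, k - 1)
            z = np.concatenate(
                [xs @ w, np.zeros((n, 1))], axis=1
            )
            lse = logsumexp(z, axis=1)
            f = float(np.mean(lse) - np.sum(p * z) / n) + neg_entropy
            q = np.exp(z - lse[:, None])
            grad = xs.T @ (q - p) / n
            return f, grad[:, : k - 1].ravel()

        res = minimize(
            objective,
            np.zeros((u + 1) * (k - 1)),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": gtol, "maxiter": maxiter, "maxfun": 10 * maxiter},
        )
        w = res.x.reshape(u + 1, k - 1)
        w_full = np.concatenate([w, np.zeros((u + 1, 1))], axis=1)
        weights = w_full[:u] / sd[:, None]
        bias = w_full[u] - mu @ weights
        return PosteriorDecoderResults(
            weights=weights,
            bias=bias,
            grid=self.grid,
            mean_kl_train=float(res.fun),
            n_train=n,
            n_iter=int(res.nit),
            converged=bool(res.success),
            message=str(res.message),
        )


@dataclass
class PosteriorDecoderResults:
    """Fitted readout: log-posterior ~ responses @ weights + bias."""

    weights: np.ndarray
    bias: np.ndarray
    grid: DelayGrid
    mean_kl_train: float
    n_train: int
    n_iter: int
    converged: bool
    message: str = ""

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    def predict_log_posterior(self, responses) -> np.ndarray:
        """Normalized decoded log-posterior, shape (n_trials, K)."""
        x = _as_rates(responses)
        if x.shape[-1] != self.n_units:
            raise ValueError(
                f"expected {self.n_units} units, got {x.shape[-1]}"
            )
        z = x @ self.weights + self.bias
        return z - logsumexp(z, axis=-1, keepdims=True)

    def predict_posterior(self, responses) -> Posterior:
        return Posterior(self.predict_log_posterior(responses), self.grid)

    def summary(self) -> str:
        lines = [
            "Posterior decoder (multinomial logistic, probabilistic targets)",
            "=" * 63,
            f"units:            {self.n_units}",
            f"classes:          {self.grid.n}",
            f"training trials:  {self.n_train}",
            f"mean train KL:    {self.mean_kl_train:.6f} nats",
            f"L-BFGS iters:     {self.n_iter} "
            f"({'converged' if self.converged else self.message})",
        ]
        return "\n".join(lines)


def decode_posterior(
    results: PosteriorDecoderResults, responses, grid: DelayGrid | None = None
) -> Posterior:
    """Reconstruct the posterior from population activity with a fitted
    readout."""
    del grid  # carried by the results object
    return results.predict_posterior(responses)


def kl_divergence(log_p: np.ndarray, log_q: np.ndarray) -> np.ndarray:
    """KL(p || q) per trial for normalized log-distributions (..., K)."""
    p = np.exp(log_p)
    return np.sum(p * (log_p - log_q), axis=-1)


@dataclass(frozen=True)
class LossReport:
    """Percent information loss of a decoded posterior set."""

    percent_info_loss: float
    kl_to_true: float
    kl_true_to_prior: float
    n_test: int
    n_train: int = 0

    def __str__(self) -> str:
        return (
            f"information loss {self.percent_info_loss:.3f}% "
            f"(mean KL {self.kl_to_true:.5f} / {self.kl_true_to_prior:.5f} "
            f"nats, n={self.n_test})"
        )


def information_loss(
    log_true: np.ndarray,
    log_decoded: np.ndarray,
    grid: DelayGrid,
    n_train: int = 0,
) -> LossReport:
    """100 x mean KL(true || decoded) / mean KL(true || prior)."""
    kl_dec = float(np.mean(kl_divergence(log_true, log_decoded)))
    kl_prior = float(
        np.mean(kl_divergence(log_true, np.broadcast_to(
            grid.log_prior, log_true.shape
        )))
    )
    if kl_prior <= 0:
        raise ValueError(
            "true posterior equals the prior on average; loss undefined"
        )
    return LossReport(
        percent_info_loss=100.0 * kl_dec / kl_prior,
        kl_to_true=kl_dec,
        kl_true_to_prior=kl_prior,
        n_test=int(np.prod(log_true.shape[:-1])),
        n_train=n_train,
    )


def split_trials(
    n: int,
    seed: int = 0,
    strata: np.ndarray | None = None,
    train_frac: float = 0.5,
) -> np.ndarray:
    """Boolean train mask, 50/50 by default, stratified when labels given."""
    rng = np.random.default_rng(seed)
    mask = np.zeros(n, dtype=bool)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        mask[idx[: int(round(train_frac * len(idx)))]] = True
    return mask
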