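"""Bayesian posterior models for subgroup-by-arm binomial outcomes.

Three models are fitted by Metropolis-within-Gibbs MCMC:

``independent``
    Each cell's log odds ``beta_jk = logit(P_jk)`` has an independent
    ``N(0, 1.82^2)`` prior (a close match to a flat ``Beta(1,1)`` prior on
    the probability scale).  Cells are a posteriori independent.

``hierarchical``
    A beta-binomial hierarchy that borrows strength across subgroups
    within an arm: ``Y_jk ~ Bin(n_jk, P_jk)``,
    ``P_jk ~ Beta(m P_k, m (1 - P_k))``, ``P_k ~ Beta(1, 1)``.  The
    borrowing strength ``m`` acts as a prior pseudo-sample size pulling
    the subgroup rates toward the arm-level mean ``P_k``.

``hierarchical_drift``
    The hierarchical model with a first-order normal dynamic linear model
    (NDLM) on analysis-period effects: outcomes in period ``t < T`` have
    ``logit(P_jkt) = logit(P_jkT) + theta_t`` with ``theta_T = 0``,
    ``theta_{t-1} ~ N(theta_t, tau)`` and ``tau ~ InvGamma(0.25, 0.1)``.
    ``tau`` is the random-walk *variance*.

The conditional ``P_jk | P_k, data`` in the hierarchical model is conjugate
(``Beta(m P_k + Y_jk, m(1-P_k) + n_jk - Y_jk)``) and is sampled directly;
all other updates are adaptive random-walk Metropolis steps on the logit
(probabilities) or identity (``theta``) scale.  Likelihoods are evaluated
as ``y log p + (n - y) log(1-p)``, which stays well defined for the
fractional pseudo-counts used to prime allocation; binomial normalizing
constants cancel in the MCMC and are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .design_core import EVT, MM, McmcSettings, TrialData, rng_stream

__all__ = [
    "PosteriorDraws",
    "fit_independent",
    "fit_hierarchical",
    "fit_drift",
    "fit_model",
    "prob_superiority",
    "prob_or_in_band",
    "posterior_variance",
    "mcse_mean",
]

_EPS = 1e-12
_INDEP_PRIOR_SD = 1.82  # prior SD of the log odds in the independent model
_TAU_SHAPE = 0.25       # InvGamma prior on the NDLM drift variance tau
_TAU_SCALE = 0.1


@dataclass
class PosteriorDraws:
    """Pooled posterior draws from one model fit.

    ``p`` has shape ``(n_draws, J, K)``; for the drift model these are the
    final-period rates ``P_jkT``.  ``hypermean`` (``P_k``, shape
    ``(n_draws, K)``) is absent for the independent model; ``theta``
    (shape ``(n_draws, T-1)``) and ``tau`` are present only for the drift
    model.
    """

    model_kind: str
    p: np.ndarray
    hypermean: np.ndarray | None = None
    theta: np.ndarray | None = None
    tau: np.ndarray | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.p.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.p.shape[1], self.p.shape[2]

    def to_table(self) -> pd.DataFrame:
        """Flat (draw, chain, parameter, value) table of all draws."""
        n_chains = int(self.diagnostics.get("n_chains", 1))
        per_chain = self.n_draws // n_chains
        chain = np.repeat(np.arange(n_chains), per_chain)
        draw = np.tile(np.arange(per_chain), n_chains)
        rows = []
        J, K = self.shape
        for j in range(J):
            for k in range(K):
                rows.append(pd.DataFrame({
                    "draw": draw, "chain": chain,
                    "parameter": f"p[{j},{k}]", "value": self.p[:, j, k],
                }))
        if self.hypermean is not None:
            for k in range(K):
                rows.append(pd.DataFrame({
                    "draw": draw, "chain": chain,
                    "parameter": f"hypermean[{k}]", "value": self.hypermean[:, k],
                }))
        if self.theta is not None:
            for t in range(self.theta.shape[1]):
                rows.append(pd.DataFrame({
                    "draw": draw, "chain": chain,
                    "parameter": f"theta[{t + 1}]", "value": self.theta[:, t],
                }))
        if self.tau is not None:
            rows.append(pd.DataFrame({
                "draw": draw, "chain": chain, "parameter": "tau", "value": self.tau,
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# small numerical helpers

def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    return np.log(p) - np.log1p(-p)


def mcse_mean(x: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of a chain mean, by batch means.

    Robust to the autocorrelation of MCMC output; falls back to the iid
    formula when the chain is too short to batch.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 2 * n_batches:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.inf
    b = n // n_batches
    means = x[: b * n_batches].reshape(n_batches, b).mean(axis=1)
    return float(np.std(means, ddof=1) / np.sqrt(n_batches))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an array of shape (n_chains, n_draws)."""
    n_chains, n = chains.shape
    if n < 4:
        return np.nan
    half = n // 2
    parts = chains[:, : 2 * half].reshape(n_chains * 2, half)
    w = parts.var(axis=1, ddof=1).mean()
    b = half * parts.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


def _rhat_summary(pooled: np.ndarray, n_chains: int) -> float:
    """Max split-R-hat across the entries of pooled (n_draws, ...) draws."""
    if n_chains < 2:
        return np.nan
    per_chain = pooled.shape[0] // n_chains
    flat = pooled.reshape(pooled.shape[0], -1)
    worst = 0.0
    for idx in range(flat.shape[1]):
        r = _split_rhat(flat[: per_chain * n_chains, idx].reshape(n_chains, per_chain))
        if np.isfinite(r):
            worst = max(worst, r)
    return worst


def _validate_counts(n: np.ndarray, y: np.ndarray) -> None:
    if np.any(n < 0) or np.any(y < 0) or np.any(y > n + 1e-9):
        raise ValueError("counts must satisfy 0 <= y <= n")


def _init_probs(n: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p0 = (y + 1.0) / (n + 2.0)
    jitter = rng.normal(scale=0.1, size=p0.shape)
    return np.clip(_expit(_logit(np.clip(p0, 0.02, 0.98)) + jitter), 1e-4, 1 - 1e-4)


def _adapt(log_scale, accepted, i, target):
    # Robbins-Monro scale adaptation on the log scale (diminishing steps)
    return log_scale + (accepted - target) / (i + 1) ** 0.6


# ---------------------------------------------------------------------------
# independent model

def fit_independent(data: TrialData, mcmc: McmcSettings,
                    stream: np.random.Generator) -> PosteriorDraws:
    """Fit the independent logistic model to period-collapsed data."""
    n2, y2 = data.collapsed()
    _validate_counts(n2, y2)
    J, K = n2.shape
    draws_per_chain = (mcmc.n_iter - mcmc.n_burn) // mcmc.thin
    out = np.empty((mcmc.n_chains, draws_per_chain, J, K))
    sigma2 = _INDEP_PRIOR_SD ** 2
    accept_total = 0.0

    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(stream.integers(2 ** 63)) if c else stream
        beta = _logit(_init_probs(n2, y2, rng))
        p = _expit(beta)
        ll = y2 * np.log(p + _EPS) + (n2 - y2) * np.log1p(-p + _EPS) - beta ** 2 / (2 * sigma2)
        log_scale = np.full((J, K), np.log(mcmc.init_scale))
        normals = rng.standard_normal((mcmc.n_iter, J, K))
        logu = np.log(rng.random((mcmc.n_iter, J, K)))
        kept = 0
        for i in range(mcmc.n_iter):
            prop = beta + np.exp(log_scale) * normals[i]
            pp = _expit(prop)
            llp = (y2 * np.log(pp + _EPS) + (n2 - y2) * np.log1p(-pp + _EPS)
                   - prop ** 2 / (2 * sigma2))
            acc = logu[i] < (llp - ll)
            beta = np.where(acc, prop, beta)
            ll = np.where(acc, llp, ll)
            if i < mcmc.n_burn:
                log_scale = _adapt(log_scale, acc, i, mcmc.target_accept)
            elif (i - mcmc.n_burn) % mcmc.thin == 0:
                out[c, kept] = _expit(beta)
                kept += 1
                accept_total += acc.mean()

    pooled = out.reshape(-1, J, K)
    diag = {
        "n_chains": mcmc.n_chains,
        "accept_rate": accept_total / max(1, mcmc.n_chains * draws_per_chain),
        "rhat_max": _rhat_summary(pooled, mcmc.n_chains),
    }
    diag["converged"] = not (np.isfinite(diag["rhat_max"]) and diag["rhat_max"] > 1.1)
    return PosteriorDraws(model_kind="independent", p=pooled, diagnostics=diag)


# ---------------------------------------------------------------------------
# hierarchical model

def _hyper_logpost(pk: np.ndarray, m: float, slp: np.ndarray, sl1p: np.ndarray,
                   J: int) -> np.ndarray:
    """Log conditional of the arm-level means P_k (logit parameterization).

    Product over subgroups of Beta(p_jk; m P_k, m(1-P_k)) densities, flat
    Beta(1,1) hyperprior, plus the logit-transform Jacobian.
    """
    a = m * pk
    b = m - a
    return ((a - 1.0) * slp + (b - 1.0) * sl1p
            - J * (gammaln(a) + gammaln(b))
            + np.log(pk) + np.log1p(-pk))


def fit_hierarchical(data: TrialData, m: float, mcmc: McmcSettings,
                     stream: np.random.Generator) -> PosteriorDraws:
    """Fit the hierarchical beta-binomial model to period-collapsed data."""
    if m <= 0:
        raise ValueError("borrowing strength m must be positive")
    n2, y2 = data.collapsed()
    _validate_counts(n2, y2)
    J, K = n2.shape
    draws_per_chain = (mcmc.n_iter - mcmc.n_burn) // mcmc.thin
    p_out = np.empty((mcmc.n_chains, draws_per_chain, J, K))
    pk_out = np.empty((mcmc.n_chains, draws_per_chain, K))
    accept_total = 0.0

    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(stream.integers(2 ** 63)) if c else stream
        p = _init_probs(n2, y2, rng)
        zk = _logit(np.clip(p.mean(axis=0), 1e-3, 1 - 1e-3))
        log_scale = np.full(K, np.log(mcmc.init_scale))
        normals = rng.standard_normal((mcmc.n_iter, K))
        logu = np.log(rng.random((mcmc.n_iter, K)))
        kept = 0
        for i in range(mcmc.n_iter):
            # conjugate update of the subgroup rates given P_k
            pk = _expit(zk)
            a = m * pk[None, :] + y2
            b = m * (1.0 - pk)[None, :] + (n2 - y2)
            p = rng.beta(a, b)
            np.clip(p, _EPS, 1.0 - _EPS, out=p)
            slp = np.log(p).sum(axis=0)
            sl1p = np.log1p(-p).sum(axis=0)
            # random-walk Metropolis on logit(P_k)
            zprop = zk + np.exp(log_scale) * normals[i]
            lt_cur = _hyper_logpost(pk, m, slp, sl1p, J)
            lt_prop = _hyper_logpost(_expit(zprop), m, slp, sl1p, J)
            acc = logu[i] < (lt_prop - lt_cur)
            zk = np.where(acc, zprop, zk)
            if i < mcmc.n_burn:
                log_scale = _adapt(log_scale, acc, i, mcmc.target_accept)
            elif (i - mcmc.n_burn) % mcmc.thin == 0:
                p_out[c, kept] = p
                pk_out[c, kept] = _expit(zk)
                kept += 1
                accept_total += acc.mean()

    pooled_p = p_out.reshape(-1, J, K)
    pooled_pk = pk_out.reshape(-1, K)
    diag = {
        "n_chains": mcmc.n_chains,
        "accept_rate": accept_total / max(1, mcmc.n_chains * draws_per_chain),
        "rhat_max": _rhat_summary(pooled_p, mcmc.n_chains),
    }
    diag["converged"] = not (np.isfinite(diag["rhat_max"]) and diag["rhat_max"] > 1.1)
    return PosteriorDraws(model_kind="hierarchical", p=pooled_p,
                          hypermean=pooled_pk, diagnostics=diag)


# ---------------------------------------------------------------------------
# hierarchical drift model

def fit_drift(data: TrialData, m: float, mcmc: McmcSettings,
              stream: np.random.Generator) -> PosteriorDraws:
    """Fit the hierarchical drift model to per-period data.

    With ``T = 1`` there are no drift effects in the likelihood and the
    model coincides with :func:`fit_hierarchical`; ``tau`` is then drawn
    from its prior (the conjugate update with zero difference terms).
    """
    if m <= 0:
        raise ValueError("borrowing strength m must be positive")
    n3, y3 = data.n, data.y
    _validate_counts(n3, y3)
    J, K, T = n3.shape
    draws_per_chain = (mcmc.n_iter - mcmc.n_burn) // mcmc.thin
    p_out = np.empty((mcmc.n_chains, draws_per_chain, J, K))
    pk_out = np.empty((mcmc.n_chains, draws_per_chain, K))
    th_out = np.empty((mcmc.n_chains, draws_per_chain, T - 1))
    tau_out = np.empty((mcmc.n_chains, draws_per_chain))
    accept_total = 0.0

    n2, y2 = data.collapsed()  # only for initialization

    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(stream.integers(2 ** 63)) if c else stream
        zT = _logit(_init_probs(n2, y2, rng))           # logit(P_jkT), (J,K)
        zk = _logit(np.clip(_expit(zT).mean(axis=0), 1e-3, 1 - 1e-3))
        theta = np.zeros(T - 1)
        tau = 0.1
        ls_cell = np.full((J, K), np.log(mcmc.init_scale))
        ls_k = np.full(K, np.log(mcmc.init_scale))
        ls_th = np.full(max(T - 1, 1), np.log(mcmc.init_scale))
        norm_cell = rng.standard_normal((mcmc.n_iter, J, K))
        logu_cell = np.log(rng.random((mcmc.n_iter, J, K)))
        norm_k = rng.standard_normal((mcmc.n_iter, K))
        logu_k = np.log(rng.random((mcmc.n_iter, K)))
        if T > 1:
            norm_th = rng.standard_normal((mcmc.n_iter, T - 1))
            logu_th = np.log(rng.random((mcmc.n_iter, T - 1)))

        def loglik_cells(z_cells: np.ndarray, th_full: np.ndarray) -> np.ndarray:
            """Binomial log likelihood per (j,k) cell, summed over periods."""
            pt = _expit(z_cells[:, :, None] + th_full[None, None, :])
            np.clip(pt, _EPS, 1.0 - _EPS, out=pt)
            return (y3 * np.log(pt) + (n3 - y3) * np.log1p(-pt)).sum(axis=2)

        kept = 0
        for i in range(mcmc.n_iter):
            th_full = np.append(theta, 0.0)
            pk = _expit(zk)
            apr = m * pk[None, :]        # Beta prior shape a = m P_k
            bpr = m * (1.0 - pk)[None, :]

            # --- final-period rates P_jkT: elementwise RW on the logit scale
            pT = _expit(zT)
            ll_cur = (loglik_cells(zT, th_full)
                      + apr * np.log(pT) + bpr * np.log1p(-pT))
            zprop = zT + np.exp(ls_cell) * norm_cell[i]
            pprop = _expit(zprop)
            np.clip(pprop, _EPS, 1.0 - _EPS, out=pprop)
            ll_prop = (loglik_cells(zprop, th_full)
                       + apr * np.log(pprop) + bpr * np.log1p(-pprop))
            acc = logu_cell[i] < (ll_prop - ll_cur)
            zT = np.where(acc, zprop, zT)
            if i < mcmc.n_burn:
                ls_cell = _adapt(ls_cell, acc, i, mcmc.target_accept)

            # --- arm-level means P_k
            pT = _expit(zT)
            np.clip(pT, _EPS, 1.0 - _EPS, out=pT)
            slp = np.log(pT).sum(axis=0)
            sl1p = np.log1p(-pT).sum(axis=0)
            zkprop = zk + np.exp(ls_k) * norm_k[i]
            lt_cur = _hyper_logpost(pk, m, slp, sl1p, J)
            lt_prop = _hyper_logpost(_expit(zkprop), m, slp, sl1p, J)
            acck = logu_k[i] < (lt_prop - lt_cur)
            zk = np.where(acck, zkprop, zk)
            if i < mcmc.n_burn:
                ls_k = _adapt(ls_k, acck, i, mcmc.target_accept)

            # --- drift effects theta_t (t < T), one-at-a-time RW
            if T > 1:
                for t in range(T - 1):
                    prop_t = theta[t] + np.exp(ls_th[t]) * norm_th[i, t]
                    lp_cur = _theta_logpost(theta[t], t, theta, zT, n3, y3, tau)
                    lp_prop = _theta_logpost(prop_t, t, theta, zT, n3, y3, tau)
                    acc_t = logu_th[i, t] < (lp_prop - lp_cur)
                    if acc_t:
                        theta[t] = prop_t
                    if i < mcmc.n_burn:
                        ls_th[t] = _adapt(ls_th[t], acc_t, i, mcmc.target_accept)

            # --- drift variance tau: conjugate inverse-gamma update
            th_full = np.append(theta, 0.0)
            ssq = float(np.sum(np.diff(th_full) ** 2))
            shape = _TAU_SHAPE + 0.5 * (T - 1)
            scale = _TAU_SCALE + 0.5 * ssq
            tau = scale / rng.gamma(shape)

            if i >= mcmc.n_burn and (i - mcmc.n_burn) % mcmc.thin == 0:
                p_out[c, kept] = _expit(zT)
                pk_out[c, kept] = _expit(zk)
                th_out[c, kept] = theta
                tau_out[c, kept] = tau
                kept += 1
                accept_total += acc.mean()

    pooled_p = p_out.reshape(-1, J, K)
    diag = {
        "n_chains": mcmc.n_chains,
        "accept_rate": accept_total / max(1, mcmc.n_chains * draws_per_chain),
        "rhat_max": _rhat_summary(pooled_p, mcmc.n_chains),
    }
    diag["converged"] = not (np.isfinite(diag["rhat_max"]) and diag["rhat_max"] > 1.1)
    return PosteriorDraws(
        model_kind="hierarchical_drift",
        p=pooled_p,
        hypermean=pk_out.reshape(-1, K),
        theta=th_out.reshape(mcmc.n_chains * draws_per_chain, T - 1),
        tau=tau_out.reshape(-1),
        diagnostics=diag,
    )


def _theta_logpost(val: float, t: int, theta: np.ndarray, zT: np.ndarray,
                   n3: np.ndarray, y3: np.ndarray, tau: float) -> float:
    """Log conditional of theta_t: period-t likelihood + NDLM neighbors."""
    pt = _expit(zT + val)
    pt = np.clip(pt, _EPS, 1.0 - _EPS)
    ll = float(np.sum(y3[:, :, t] * np.log(pt) + (n3[:, :, t] - y3[:, :, t]) * np.log1p(-pt)))
    Tm1 = theta.size
    right = theta[t + 1] if t + 1 < Tm1 else 0.0  # theta_T = 0
    lp = -0.5 * (val - right) ** 2 / tau
    if t > 0:
        lp += -0.5 * (theta[t - 1] - val) ** 2 / tau
    return ll + lp


def fit_model(model_kind: str, data: TrialData, m: float, mcmc: McmcSettings,
              stream: np.random.Generator) -> PosteriorDraws:
    """Dispatch to the configured model.

    The non-drift models see the data collapsed over periods; the drift
    model sees the per-period counts.
    """
    if model_kind == "independent":
        return fit_independent(data, mcmc, stream)
    if model_kind == "hierarchical":
        return fit_hierarchical(data, m, mcmc, stream)
    if model_kind == "hierarchical_drift":
        return fit_drift(data, m, mcmc, stream)
    raise ValueError(f"unknown model kind {model_kind!r}")


# ---------------------------------------------------------------------------
# posterior decision quantities

def prob_superiority(draws: PosteriorDraws, j: int, k: int, k_prime: int) -> float:
    """Posterior probability that arm ``k`` beats ``k_prime`` in subgroup ``j``.

    The fraction of draws with ``P_jk - P_jk' > 0`` (strict; ties count
    as not superior).
    """
    if k == k_prime:
        raise ValueError("arms k and k_prime must differ")
    return float(np.mean(draws.p[:, j, k] > draws.p[:, j, k_prime]))


def prob_or_in_band(draws: PosteriorDraws, j: int, lo: float = 0.8,
                    hi: float = 1.2) -> float:
    """Posterior probability that the MM:EVT odds ratio lies in (lo, hi).

    ``OR_j = (P_jMM / (1 - P_jMM)) / (P_jEVT / (1 - P_jEVT))``.
    """
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    p_mm = draws.p[:, j, MM]
    p_evt = draws.p[:, j, EVT]
    or_j = (p_mm / (1.0 - p_mm)) / (p_evt / (1.0 - p_evt))
    return float(np.mean((or_j > lo) & (or_j < hi)))


def posterior_variance(draws: PosteriorDraws, j: int, k: int) -> float:
    """Sample variance (denominator n-1) of the P_jk draws."""
    if draws.n_draws < 2:
        raise ValueError("need at least 2 draws")
    return float(np.var(draws.p[:, j, k], ddof=1))
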