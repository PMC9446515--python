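"""Shared fixtures and independent numerical oracles for the test suite.

The oracles here deliberately avoid the package's MCMC code paths: they
integrate the small-model posteriors by deterministic quadrature, using
the conjugacy of the beta-binomial hierarchy to reduce the integrals to
one dimension.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import betaln, expit

from platformsim.design_core import DesignConfig, McmcSettings


# ---------------------------------------------------------------------------
# independent quadrature oracles

def indep_oracle_mean(y: float, n: float, sd: float = 1.82,
                      lo: float = -10.0, hi: float = 10.0, k: int = 20001) -> float:
    """Posterior mean of P for one cell of the independent logistic model.

    Deterministic 1-D quadrature over the log odds beta on [lo, hi].
    """
    b = np.linspace(lo, hi, k)
    p = expit(b)
    logw = y * np.log(p) + (n - y) * np.log1p(-p) - b ** 2 / (2 * sd ** 2)
    w = np.exp(logw - logw.max())
    return float(np.trapezoid(w * p, b) / np.trapezoid(w, b))


def hier_oracle_means(ys, ns, m: float = 1.0, k: int = 20001):
    """Posterior means of the subgroup rates in a K=1 hierarchical model.

    Exploits beta-binomial conjugacy: given the arm mean P_k, each
    subgroup integrates analytically, leaving a single quadrature over
    P_k.  Returns (per-subgroup means, mean of P_k).
    """
    pk = np.linspace(1e-6, 1 - 1e-6, k)
    a, b = m * pk, m * (1.0 - pk)
    logw = np.zeros_like(pk)
    cond_means = []
    for y, n in zip(ys, ns):
        logw += betaln(a + y, b + n - y) - betaln(a, b)
    w = np.exp(logw - logw.max())
    z = np.trapezoid(w, pk)
    for y, n in zip(ys, ns):
        cond = (a + y) / (m + n)
        cond_means.append(float(np.trapezoid(w * cond, pk) / z))
    mean_pk = float(np.trapezoid(w * pk, pk) / z)
    return cond_means, mean_pk


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def fast_mcmc() -> McmcSettings:
    """Short single-chain settings for simulation sweeps."""
    return McmcSettings(n_iter=1500, n_burn=500, n_chains=1)


@pytest.fixture(scope="session")
def std_mcmc() -> McmcSettings:
    """Two-chain settings long enough for oracle comparisons."""
    return McmcSettings(n_iter=6000, n_burn=1000, n_chains=2)


@pytest.fixture(scope="session")
def tiny_mcmc() -> McmcSettings:
    """Very short settings for plumbing tests where accuracy is irrelevant."""
    return McmcSettings(n_iter=400, n_burn=100, n_chains=1)


@pytest.fixture(scope="session")
def reduced_config(fast_mcmc) -> DesignConfig:
    """The desk-scale design: 1,000 participants, analyses every 250."""
    return DesignConfig(
        total_enrollment=1000,
        interim_milestones=(250, 500, 750, 1000),
        model_kind="hierarchical",
        m=30.0,
        scheme="rarcomp",
        mcmc=fast_mcmc,
    )


@pytest.fixture()
def tiny_config(tiny_mcmc) -> DesignConfig:
    """A two-subgroup micro design for fast plumbing tests."""
    return DesignConfig(
        n_subgroups=2,
        subgroup_proportions=(0.5, 0.5),
        total_enrollment=100,
        interim_milestones=(50, 100),
        model_kind="hierarchical",
        m=10.0,
        scheme="rarcomp",
        gamma=0.95,
        pseudo_rates=((0.3, 0.5), (0.4, 0.6)),
        mcmc=tiny_mcmc,
    )
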