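"""Interim decision logic and randomization-probability rules.

At each analysis, every still-continuing subgroup is tested in order:
superiority first (posterior probability of a treatment difference above
the threshold ``gamma`` locks all future allocation to the superior arm),
then equivalence (enough posterior mass of the MM:EVT odds ratio inside
the band locks allocation to the cheaper MM arm).  If neither gate fires,
the next participant's allocation probabilities come from the configured
scheme:

``fixed``    1:1 allocation, ``V_jk = 1/K = 0.5``.
``rar``      response-adaptive: ``V_jk ∝ sqrt(P(P_jk - P_jk' > 0) * Var(P_jk) / (n_jk + 1))``.
``rarcomp``  the compromise scheme: the arithmetic mean of the RAR
             probability and 0.5, which confines allocation to [0.25, 0.75].

Decisions are terminal: once a subgroup locks, it is never re-tested.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .design_core import EVT, MM, DesignConfig, TrialData
from .posterior_models import (
    PosteriorDraws,
    posterior_variance,
    prob_or_in_band,
    prob_superiority,
)

__all__ = [
    "Status",
    "SubgroupDecision",
    "make_pseudo_data",
    "check_superiority",
    "check_equivalence",
    "rar_probs",
    "rarcomp_probs",
    "fixed_probs",
    "allocation_from_draws",
    "interim_decision",
]


class Status(str, enum.Enum):
    """Terminal status of a subgroup's treatment comparison."""

    CONTINUING = "continuing"
    SUPERIORITY_EVT = "superiority_EVT"
    SUPERIORITY_MM = "superiority_MM"
    EQUIVALENCE = "equivalence"


@dataclass(frozen=True)
class SubgroupDecision:
    """Per-subgroup decision state: status and the analysis that set it.

    ``declared_at`` is the 1-based analysis index at which a non-continuing
    status was first declared (None while continuing).  Statuses never
    revert.
    """

    statuses: tuple[Status, ...]
    declared_at: tuple[int | None, ...]

    @classmethod
    def all_continuing(cls, J: int) -> "SubgroupDecision":
        return cls(statuses=(Status.CONTINUING,) * J, declared_at=(None,) * J)

    def is_locked(self, j: int) -> bool:
        return self.statuses[j] is not Status.CONTINUING

    def with_status(self, j: int, status: Status, analysis: int) -> "SubgroupDecision":
        if self.is_locked(j):
            raise ValueError(f"subgroup {j} already locked as {self.statuses[j].value}")
        st = list(self.statuses)
        at = list(self.declared_at)
        st[j] = status
        at[j] = analysis
        return replace(self, statuses=tuple(st), declared_at=tuple(at))


def make_pseudo_data(pseudo_rates: np.ndarray, n0: float) -> TrialData:
    """Pseudo-dataset priming the initial allocation of adaptive schemes.

    Every subgroup-arm cell gets ``n0`` observations and a (generally
    fractional) favorable-outcome count ``rate * n0``.  ``n0 = 0`` yields
    empty data, i.e. no prior priming.
    """
    rates = np.asarray(pseudo_rates, dtype=float)
    if np.any(rates <= 0) or np.any(rates >= 1):
        raise ValueError("pseudo rates must lie strictly in (0, 1)")
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    n = np.full(rates.shape, float(n0))[:, :, None]
    y = (rates * float(n0))[:, :, None]
    return TrialData(n, y)


def check_superiority(p_sup_evt: float, p_sup_mm: float, gamma: float) -> Status | None:
    """Superiority gate: strict ``> gamma`` in either direction, EVT tested first.

    With ``gamma > 0.5`` at most one direction can exceed the threshold.
    """
    if p_sup_evt > gamma:
        return Status.SUPERIORITY_EVT
    if p_sup_mm > gamma:
        return Status.SUPERIORITY_MM
    return None


def check_equivalence(p_in_band: float, threshold: float = 0.7) -> bool:
    """Equivalence gate: strict ``> threshold`` posterior mass in the OR band."""
    return p_in_band > threshold


def rar_probs(p_sup: np.ndarray, var: np.ndarray, n: np.ndarray) -> np.ndarray:
    """RAR allocation probabilities for one subgroup.

    Unnormalized weights ``w_k = sqrt(p_sup_k * var_k / (n_k + 1))``,
    normalized to sum to 1.  If both weights vanish the allocation falls
    back to 0.5/0.5.
    """
    p_sup = np.asarray(p_sup, dtype=float)
    var = np.asarray(var, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(var < 0) or np.any(n < 0):
        raise ValueError("variances and counts must be nonnegative")
    w = np.sqrt(p_sup * var / (n + 1.0))
    total = w.sum()
    if total <= 0:
        return np.array([0.5, 0.5])
    return w / total


def rarcomp_probs(rar: np.ndarray) -> np.ndarray:
    """RARCOMP: average of the RAR entry and the fixed 0.5 entry, per arm."""
    rar = np.asarray(rar, dtype=float)
    if abs(rar.sum() - 1.0) > 1e-9:
        raise ValueError("RAR probabilities must sum to 1")
    return (rar + 0.5) / 2.0


def fixed_probs() -> np.ndarray:
    """Fixed 1:1 allocation."""
    return np.array([0.5, 0.5])


def _lock_alloc(status: Status) -> np.ndarray:
    if status is Status.SUPERIORITY_EVT:
        return np.array([0.0, 1.0])
    # superiority of MM and equivalence both send everyone to MM
    return np.array([1.0, 0.0])


def allocation_from_draws(draws: PosteriorDraws, scheme: str, counts: np.ndarray,
                          j: int) -> np.ndarray:
    """Scheme allocation probabilities (v_MM, v_EVT) for subgroup ``j``.

    ``counts`` are the current real enrollment totals per (subgroup, arm);
    they enter the RAR weight through ``Var(P_jk) / (n_jk + 1)``.
    """
    if scheme == "fixed":
        return fixed_probs()
    p_sup = np.array([
        prob_superiority(draws, j, MM, EVT),
        prob_superiority(draws, j, EVT, MM),
    ])
    var = np.array([
        posterior_variance(draws, j, MM),
        posterior_variance(draws, j, EVT),
    ])
    v = rar_probs(p_sup, var, np.asarray(counts[j], dtype=float))
    if scheme == "rarcomp":
        v = rarcomp_probs(v)
    elif scheme != "rar":
        raise ValueError(f"unknown allocation scheme {scheme!r}")
    return v


def interim_decision(
    draws: PosteriorDraws,
    config: DesignConfig,
    prior_status: SubgroupDecision,
    counts: np.ndarray,
    analysis: int,
) -> tuple[SubgroupDecision, np.ndarray, list[dict]]:
    """Apply the decision flowchart at one analysis.

    For every continuing subgroup, in order: the superiority gate (which
    locks all future allocation to the superior arm), then the
    equivalence gate (which locks allocation to MM), then the configured
    scheme's allocation probabilities.  Locked subgroups pass through
    unchanged.  Returns the updated decision state, a (J, 2) allocation
    matrix, and a per-subgroup trace of the posterior quantities.
    """
    J = config.n_subgroups
    decision = prior_status
    alloc = np.empty((J, 2))
    trace: list[dict] = []
    lo, hi = config.equiv_band
    for j in range(J):
        if decision.is_locked(j):
            alloc[j] = _lock_alloc(decision.statuses[j])
            continue
        p_sup_evt = prob_superiority(draws, j, EVT, MM)
        p_sup_mm = prob_superiority(draws, j, MM, EVT)
        p_band = prob_or_in_band(draws, j, lo, hi)
        sup = check_superiority(p_sup_evt, p_sup_mm, config.gamma)
        if sup is not None:
            decision = decision.with_status(j, sup, analysis)
            alloc[j] = _lock_alloc(sup)
        elif check_equivalence(p_band, config.equiv_threshold):
            decision = decision.with_status(j, Status.EQUIVALENCE, analysis)
            alloc[j] = _lock_alloc(Status.EQUIVALENCE)
        else:
            alloc[j] = allocation_from_draws(draws, config.scheme, counts, j)
        trace.append({
            "analysis": analysis,
            "subgroup": j,
            "p_sup_EVT": p_sup_evt,
            "p_sup_MM": p_sup_mm,
            "p_OR_in_band": p_band,
            "status": decision.statuses[j].value,
            "v_MM": float(alloc[j, MM]),
            "v_EVT": float(alloc[j, EVT]),
        })
    return decision, alloc, trace
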