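"""End-to-end simulation of a single adaptive platform trial.

A trial enrolls participants sequentially under Poisson weekly accrual.
Participants enrolled between two analysis milestones form one analysis
period.  At each milestone the configured model is fitted to all real
data accumulated so far (pseudo-data never enter interim or final
analyses), the decision flowchart is applied per subgroup, and the
allocation probabilities for the next period are updated.  The fixed 1:1
design has no interims: its single analysis happens at full enrollment.

Outcomes are available immediately: the 90-day outcome lag is not
modeled, so every enrolled participant contributes to the next analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .design_core import (
    ARMS,
    EVT,
    MM,
    DesignConfig,
    ScenarioSpec,
    TrialData,
    rng_stream,
)
from .allocation_rules import (
    SubgroupDecision,
    interim_decision,
    make_pseudo_data,
    allocation_from_draws,
    fixed_probs,
)
from .posterior_models import fit_model

__all__ = [
    "TrialResult",
    "simulate_accrual",
    "assign_membership",
    "assign_treatment",
    "generate_outcome",
    "run_trial",
]


@dataclass
class TrialResult:
    """Complete record of one simulated trial."""

    scenario_name: str
    scheme: str
    model_kind: str
    seed: int
    decision: SubgroupDecision
    data: TrialData                      # real counts, (J, K, n_periods)
    alloc_history: np.ndarray            # (n_analyses, J, 2); row t-1 governs period t
    decision_trace: list[dict] = field(default_factory=list)
    weeks_to_milestones: tuple[int, ...] = ()

    @property
    def total_enrollment(self) -> int:
        return int(self.data.n.sum())

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.decision_trace)

    def to_dict(self) -> dict[str, Any]:
        return {
            "scenario": self.scenario_name,
            "scheme": self.scheme,
            "model_kind": self.model_kind,
            "seed": self.seed,
            "statuses": [s.value for s in self.decision.statuses],
            "declared_at": list(self.decision.declared_at),
            "n": self.data.n.tolist(),
            "y": self.data.y.tolist(),
            "alloc_history": self.alloc_history.tolist(),
            "weeks_to_milestones": list(self.weeks_to_milestones),
            "decision_trace": self.decision_trace,
        }

    def to_json(self, **kw: Any) -> str:
        return json.dumps(self.to_dict(), **kw)


def simulate_accrual(rate: float, total: int, stream: np.random.Generator) -> np.ndarray:
    """Weekly enrollment counts: iid Poisson(rate), truncated at ``total``.

    The last week's count is clipped so the cumulative sum equals exactly
    ``total``.
    """
    if rate <= 0:
        raise ValueError("accrual rate must be positive")
    if total <= 0:
        return np.zeros(0, dtype=int)
    weeks: list[int] = []
    enrolled = 0
    while enrolled < total:
        block = stream.poisson(rate, size=64)
        for w in block:
            w = int(min(w, total - enrolled))
            weeks.append(w)
            enrolled += w
            if enrolled >= total:
                break
    return np.asarray(weeks, dtype=int)


def assign_membership(proportions: np.ndarray, stream: np.random.Generator) -> int:
    """Draw one participant's subgroup index from the population mix."""
    return int(_memberships(np.asarray(proportions, float), 1, stream)[0])


def assign_treatment(v: np.ndarray, stream: np.random.Generator) -> int:
    """Assign one participant: EVT with probability ``v[EVT]``, else MM."""
    v = np.asarray(v, dtype=float)
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("allocation probabilities must sum to 1")
    return EVT if stream.random() < v[EVT] else MM


def generate_outcome(scenario: ScenarioSpec, j: int, k: int, period: int,
                     n_periods: int, stream: np.random.Generator) -> int:
    """Draw one binary outcome for subgroup ``j``, arm ``k`` in ``period``.

    The success probability is ``expit(logit(P_jkT) + theta_period)`` when
    the scenario carries a drift profile, and ``P_jkT`` otherwise.
    """
    rate = scenario.rates_at_period(period, n_periods)[j, k]
    return int(stream.random() < rate)


def _memberships(props: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(props)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(size), side="right")


def run_trial(config: DesignConfig, scenario: ScenarioSpec,
              seed: int | None = None, trial_id: int = 0) -> TrialResult:
    """Simulate one complete trial under ``scenario``.

    Deterministic given ``(config, scenario, seed, trial_id)``: all
    randomness flows through substreams of the master seed, so repeated
    calls are bit-identical and independent trials use distinct
    ``trial_id`` values.
    """
    if seed is None:
        seed = config.seed
    J, K = config.n_subgroups, config.n_arms
    if scenario.n_subgroups != J or scenario.n_arms != K:
        raise ValueError(
            f"scenario {scenario.name!r} is {scenario.n_subgroups}x{scenario.n_arms}, "
            f"design expects {J}x{K}"
        )
    n_periods = config.n_periods
    if scenario.theta_profile is not None and len(scenario.theta_profile) != n_periods:
        raise ValueError(
            f"scenario drift profile has {len(scenario.theta_profile)} periods, "
            f"design has {n_periods} analyses"
        )
    props = np.asarray(config.subgroup_proportions, dtype=float)
    adaptive = config.scheme != "fixed"

    # --- initial allocation --------------------------------------------
    # Adaptive schemes prime the first period's allocation by fitting the
    # configured model to the pseudo-dataset alone (the drift model
    # degenerates to one period there).  No decision can be made from
    # pseudo-data; the fixed scheme always starts (and stays) at 0.5.
    if adaptive and config.pseudo_n0 > 0:
        pseudo = make_pseudo_data(np.asarray(config.pseudo_rates), config.pseudo_n0)
        pseudo_draws = fit_model(config.model_kind, pseudo, config.m, config.mcmc,
                                 rng_stream(seed, trial_id, 3))
        zero_counts = np.zeros((J, K))
        alloc = np.stack([
            allocation_from_draws(pseudo_draws, config.scheme, zero_counts, j)
            for j in range(J)
        ])
    else:
        alloc = np.tile(fixed_probs(), (J, 1))

    n = np.zeros((J, K, n_periods))
    y = np.zeros((J, K, n_periods))
    alloc_history = np.empty((n_periods, J, K))
    decision = SubgroupDecision.all_continuing(J)
    trace: list[dict] = []

    boundaries = (0,) + tuple(config.interim_milestones)
    for t in range(1, n_periods + 1):
        alloc_history[t - 1] = alloc
        block = boundaries[t] - boundaries[t - 1]
        rng_t = rng_stream(seed, trial_id, 1, t)
        member = _memberships(props, block, rng_t)
        v_evt = alloc[member, EVT]
        arm = (rng_t.random(block) < v_evt).astype(int)
        rates = scenario.rates_at_period(t, n_periods)
        outcome = rng_t.random(block) < rates[member, arm]
        np.add.at(n, (member, arm, np.full(block, t - 1)), 1.0)
        np.add.at(y, (member, arm, np.full(block, t - 1)), outcome.astype(float))

        final = t == n_periods
        if adaptive or final:
            data_t = TrialData(n[:, :, :t], y[:, :, :t])
            draws = fit_model(config.model_kind, data_t, config.m, config.mcmc,
                              rng_stream(seed, trial_id, 2, t))
            counts = data_t.collapsed()[0]
            decision, alloc, step_trace = interim_decision(
                draws, config, decision, counts, analysis=t
            )
            trace.extend(step_trace)

    accrual = simulate_accrual(config.accrual_rate, config.total_enrollment,
                               rng_stream(seed, trial_id, 0))
    cum = np.cumsum(accrual)
    weeks = tuple(int(np.searchsorted(cum, ms) + 1) for ms in config.interim_milestones)

    return TrialResult(
        scenario_name=scenario.name,
        scheme=config.scheme,
        model_kind=config.model_kind,
        seed=seed,
        decision=decision,
        data=TrialData(n, y),
        alloc_history=alloc_history,
        decision_trace=trace,
        weeks_to_milestones=weeks,
    )


def participants_frame(result: TrialResult, config: DesignConfig,
                       scenario: ScenarioSpec) -> pd.DataFrame:
    """Regenerate the per-participant table of a trial.

    Replays the trial's random streams, so the rows match the counts in
    ``result.data`` exactly.
    """
    res2 = run_trial(config, scenario, seed=result.seed)
    if not np.array_equal(res2.data.n, result.data.n):
        raise ValueError("result does not correspond to (config, scenario, seed)")
    props = np.asarray(config.subgroup_proportions, dtype=float)
    boundaries = (0,) + tuple(config.interim_milestones)
    accrual = simulate_accrual(config.accrual_rate, config.total_enrollment,
                               rng_stream(result.seed, 0, 0))
    week_of = np.repeat(np.arange(1, accrual.size + 1), accrual)
    rows = []
    for t in range(1, config.n_periods + 1):
        block = boundaries[t] - boundaries[t - 1]
        rng_t = rng_stream(result.seed, 0, 1, t)
        member = _memberships(props, block, rng_t)
        v_evt = result.alloc_history[t - 1][member, EVT]
        arm = (rng_t.random(block) < v_evt).astype(int)
        rates = scenario.rates_at_period(t, config.n_periods)
        outcome = (rng_t.random(block) < rates[member, arm]).astype(int)
        ids = np.arange(boundaries[t - 1], boundaries[t])
        rows.append(pd.DataFrame({
            "id": ids,
            "week": week_of[ids],
            "subgroup": member,
            "arm": [ARMS[a] for a in arm],
            "period": t,
            "outcome": outcome,
        }))
    return pd.concat(rows, ignore_index=True)
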