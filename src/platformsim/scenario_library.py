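"""Canonical truth-generating scenarios for the simulation studies.

Five named scenarios cover the null ("Equal"), the anticipated effect
("Expected"), its reversal ("Reversed"), a larger effect ("ExtremeEVT")
and an effect confined to a single subgroup ("SingleSubgroup").  Each is a
matrix of favorable-outcome probabilities per subgroup (rows, canonical
order) and arm (MM, EVT).  A linear logit-scale drift profile can be
attached to any scenario to emulate response rates that were higher early
in the trial and settle to the final-period values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .design_core import ScenarioSpec

__all__ = [
    "SCENARIO_NAMES",
    "LINEAR_DRIFT_THETA",
    "get_scenario",
    "with_linear_drift",
    "custom_scenario",
]

# Rows: Large Core Only; Mild Deficit Only; Distal Occlusion Only;
#       Distal Occlusion + Large core; Distal Occlusion + Mild Deficit.
# Columns: (MM, EVT).
_SCENARIOS: dict[str, tuple[tuple[float, float], ...]] = {
    "Equal": (
        (0.10, 0.10),
        (0.70, 0.70),
        (0.35, 0.35),
        (0.25, 0.25),
        (0.75, 0.75),
    ),
    "Expected": (
        (0.10, 0.25),
        (0.70, 0.84),
        (0.35, 0.55),
        (0.25, 0.45),
        (0.75, 0.85),
    ),
    "Reversed": (
        (0.25, 0.10),
        (0.84, 0.70),
        (0.55, 0.35),
        (0.45, 0.25),
        (0.85, 0.75),
    ),
    "ExtremeEVT": (
        (0.10, 0.30),
        (0.70, 0.89),
        (0.35, 0.60),
        (0.25, 0.50),
        (0.75, 0.90),
    ),
    "SingleSubgroup": (
        (0.25, 0.45),
        (0.84, 0.84),
        (0.55, 0.55),
        (0.45, 0.45),
        (0.85, 0.85),
    ),
}

SCENARIO_NAMES: tuple[str, ...] = tuple(_SCENARIOS)

#: Linear drift profile over the four analysis periods: log odds start
#: 0.75 above the final-period value and decrease linearly to 0.
LINEAR_DRIFT_THETA: tuple[float, ...] = (0.75, 0.50, 0.25, 0.0)


def get_scenario(name: str) -> ScenarioSpec:
    """Return the named library scenario (no drift attached)."""
    try:
        rates = _SCENARIOS[name]
    except KeyError:
        valid = ", ".join(SCENARIO_NAMES)
        raise KeyError(f"unknown scenario {name!r}; valid names: {valid}") from None
    return ScenarioSpec(name=name, true_rates=rates)


def with_linear_drift(spec: ScenarioSpec, theta: Sequence[float] = LINEAR_DRIFT_THETA) -> ScenarioSpec:
    """Attach the linear drift profile to a drift-free scenario.

    The profile shifts each period's log odds by ``theta[t-1]``; the last
    entry is 0, so final-period rates equal the scenario's ``true_rates``.
    """
    if spec.theta_profile is not None:
        raise ValueError(f"scenario {spec.name!r} already has a drift profile")
    return ScenarioSpec(
        name=f"{spec.name}+drift",
        true_rates=spec.true_rates,
        theta_profile=tuple(float(t) for t in theta),
    )


def custom_scenario(
    rates: Sequence[Sequence[float]],
    theta: Sequence[float] | None = None,
    name: str = "custom",
) -> ScenarioSpec:
    """Build a validated user scenario from a (subgroup x arm) rate matrix."""
    mat = np.asarray(rates, dtype=float)
    return ScenarioSpec(
        name=name,
        true_rates=tuple(tuple(float(v) for v in row) for row in mat),
        theta_profile=None if theta is None else tuple(float(t) for t in theta),
    )
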