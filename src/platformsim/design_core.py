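"""Core domain types, configuration validation and seeded random streams.

The trial simulated here is a two-arm (medical management ``MM`` vs
endovascular thrombectomy ``EVT``), multi-subgroup platform trial for a
binary 90-day outcome.  Everything downstream — posterior models,
allocation rules, the trial engine and the operating-characteristic
machinery — shares the types defined in this module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ARMS",
    "MM",
    "EVT",
    "SUBGROUP_LABELS",
    "McmcSettings",
    "DesignConfig",
    "ScenarioSpec",
    "TrialData",
    "validate_config",
    "load_config",
    "rng_stream",
]

#: Arm labels in index order.  MM (medical management) is the reference arm.
ARMS: tuple[str, str] = ("MM", "EVT")
MM: int = 0
EVT: int = 1

#: The five mutually exclusive stroke-patient subgroups, in canonical order.
SUBGROUP_LABELS: tuple[str, ...] = (
    "Large Core Only",
    "Mild Deficit Only",
    "Distal Occlusion Only",
    "Distal Occlusion + Large core",
    "Distal Occlusion + Mild Deficit",
)

#: Prior beliefs about the favorable-outcome rate per subgroup and arm,
#: used only to prime the very first allocation via a pseudo-dataset.
DEFAULT_PSEUDO_RATES: tuple[tuple[float, float], ...] = (
    (0.10, 0.25),
    (0.70, 0.84),
    (0.35, 0.55),
    (0.25, 0.45),
    (0.75, 0.85),
)


def rng_stream(seed: int, *stream_id: int) -> np.random.Generator:
    """Return a deterministic, independent random substream.

    Streams are derived from ``SeedSequence(seed)`` with ``stream_id`` as
    the spawn key, so ``(seed, stream_id)`` pairs reproduce identical
    sequences while distinct ids (or seeds) give statistically independent
    generators regardless of the order in which they are created.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(s) for s in stream_id))
    return np.random.default_rng(ss)


def _as_tuple2d(x: Any) -> tuple[tuple[float, ...], ...]:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D (subgroup x arm) array")
    return tuple(tuple(float(v) for v in row) for row in a)


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings for the Metropolis-within-Gibbs fits.

    ``n_iter`` counts iterations per chain *including* burn-in; the number
    of retained draws is ``(n_iter - n_burn) // thin`` per chain.
    """

    n_iter: int = 6000
    n_burn: int = 1000
    n_chains: int = 2
    thin: int = 1
    target_accept: float = 0.44  # Robbins-Monro target for scalar RW updates
    init_scale: float = 0.5     # initial random-walk proposal SD (logit scale)

    def __post_init__(self) -> None:
        if self.n_burn < 0 or self.n_iter <= self.n_burn:
            raise ValueError("McmcSettings: need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("McmcSettings: thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("McmcSettings: n_chains must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("McmcSettings: target_accept must be in (0,1)")

    @property
    def n_draws(self) -> int:
        """Total retained draws across chains."""
        return ((self.n_iter - self.n_burn) // self.thin) * self.n_chains


@dataclass(frozen=True)
class DesignConfig:
    """Complete specification of the trial design.

    Defaults reproduce the motivating design: 10,000 participants, interim
    analyses after every 2,500 enrollments, Poisson(52) weekly accrual,
    hierarchical beta-binomial model with borrowing strength ``m``, and a
    pseudo-dataset of ``pseudo_n0 = 10`` observations per subgroup-arm cell
    that primes the initial allocation of the adaptive schemes.
    """

    n_subgroups: int = 5
    n_arms: int = 2
    subgroup_proportions: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    total_enrollment: int = 10_000
    interim_milestones: tuple[int, ...] = (2_500, 5_000, 7_500, 10_000)
    accrual_rate: float = 52.0
    model_kind: str = "hierarchical"  # independent | hierarchical | hierarchical_drift
    m: float = 30.0
    gamma: float = 0.995
    equiv_band: tuple[float, float] = (0.8, 1.2)
    equiv_threshold: float = 0.7
    scheme: str = "rarcomp"  # fixed | rar | rarcomp
    pseudo_n0: float = 10.0
    pseudo_rates: tuple[tuple[float, ...], ...] = DEFAULT_PSEUDO_RATES
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        J, K = self.n_subgroups, self.n_arms
        if K != 2:
            raise ValueError("n_arms: only two-arm designs (MM vs EVT) are supported")
        if J < 1:
            raise ValueError("n_subgroups must be >= 1")
        props = np.asarray(self.subgroup_proportions, dtype=float)
        if props.shape != (J,):
            raise ValueError("subgroup_proportions: length must equal n_subgroups")
        if np.any(props < 0) or np.any(props > 1):
            raise ValueError("subgroup_proportions: entries must lie in [0,1]")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subgroup_proportions: must sum to 1 (tolerance 1e-9)")
        ms = self.interim_milestones
        if len(ms) < 1 or any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("interim_milestones: must be non-empty and strictly increasing")
        if ms[-1] != self.total_enrollment:
            raise ValueError("interim_milestones: last milestone must equal total_enrollment")
        if ms[0] <= 0:
            raise ValueError("interim_milestones: milestones must be positive")
        if self.accrual_rate <= 0:
            raise ValueError("accrual_rate: must be positive")
        if self.model_kind not in ("independent", "hierarchical", "hierarchical_drift"):
            raise ValueError(f"model_kind: unknown model {self.model_kind!r}")
        if self.scheme not in ("fixed", "rar", "rarcomp"):
            raise ValueError(f"scheme: unknown allocation scheme {self.scheme!r}")
        if self.m <= 0:
            raise ValueError("m: borrowing strength must be positive")
        if not 0.5 < self.gamma < 1.0:
            raise ValueError("gamma: superiority threshold must lie in (0.5, 1)")
        lo, hi = self.equiv_band
        if not (0 < lo < 1 < hi):
            raise ValueError("equiv_band: need 0 < lo < 1 < hi")
        if not 0.0 < self.equiv_threshold < 1.0:
            raise ValueError("equiv_threshold: must lie in (0, 1)")
        if self.pseudo_n0 < 0:
            raise ValueError("pseudo_n0: must be nonnegative")
        pr = np.asarray(self.pseudo_rates, dtype=float)
        if pr.shape != (J, K):
            raise ValueError("pseudo_rates: shape must be (n_subgroups, n_arms)")
        if np.any(pr <= 0) or np.any(pr >= 1):
            raise ValueError("pseudo_rates: rates must lie strictly in (0, 1)")

    # -- convenience -------------------------------------------------------
    @property
    def n_periods(self) -> int:
        """Number of analysis periods (= number of analyses)."""
        return len(self.interim_milestones)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DesignConfig":
        d = dict(d)
        if "mcmc" in d and isinstance(d["mcmc"], Mapping):
            d["mcmc"] = McmcSettings(**d["mcmc"])
        for key in ("subgroup_proportions", "interim_milestones"):
            if key in d:
                d[key] = tuple(d[key])
        if "equiv_band" in d:
            d["equiv_band"] = tuple(d["equiv_band"])
        if "pseudo_rates" in d:
            d["pseudo_rates"] = _as_tuple2d(d["pseudo_rates"])
        return cls(**d)


# Sections accepted in structured config documents (YAML/JSON).
_CONFIG_SECTIONS = {
    "design": ("n_subgroups", "n_arms", "subgroup_proportions", "total_enrollment",
               "interim_milestones", "accrual_rate"),
    "model": ("model_kind", "m"),
    "allocation": ("scheme", "gamma", "equiv_band", "equiv_threshold",
                   "pseudo_n0", "pseudo_rates"),
    "mcmc": (),
    "seeds": ("seed",),
}


def validate_config(raw: Mapping[str, Any]) -> DesignConfig:
    """Validate a raw key-value document and return a :class:`DesignConfig`.

    Accepts either a flat mapping of ``DesignConfig`` field names or a
    sectioned document with ``design`` / ``model`` / ``allocation`` /
    ``mcmc`` / ``seeds`` groups.  Missing keys take the documented
    defaults; invariant violations raise ``ValueError`` naming the field.
    """
    flat: dict[str, Any] = {}
    for key, val in raw.items():
        if key in _CONFIG_SECTIONS:
            if val is None:
                continue
            if key == "mcmc":
                flat["mcmc"] = McmcSettings(**val)
            else:
                allowed = _CONFIG_SECTIONS[key]
                for k2, v2 in val.items():
                    if k2 not in allowed:
                        raise ValueError(f"unknown key {k2!r} in config section {key!r}")
                    flat[k2] = v2
        else:
            flat[key] = val
    return DesignConfig.from_dict(flat)


def load_config(path: str) -> DesignConfig:
    """Load and validate a YAML or JSON config document from ``path``."""
    with open(path) as fh:
        text = fh.read()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(raw, Mapping):
        raise ValueError(f"config file {path} does not contain a mapping")
    return validate_config(raw)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Truth-generating scenario: final-period rates and optional drift.

    ``true_rates[j, k]`` is the probability of a favorable outcome for
    subgroup ``j`` under arm ``k`` *at the final analysis period*.  An
    optional ``theta_profile`` adds a logit-scale shift per analysis
    period; the last entry must be exactly 0 so the final period matches
    ``true_rates``.
    """

    name: str
    true_rates: tuple[tuple[float, ...], ...]
    theta_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        rates = np.asarray(self.true_rates, dtype=float)
        if rates.ndim != 2:
            raise ValueError("true_rates: expected a (subgroup x arm) matrix")
        if np.any(rates <= 0) or np.any(rates >= 1):
            raise ValueError("true_rates: rates must lie strictly in (0, 1)")
        if self.theta_profile is not None:
            th = np.asarray(self.theta_profile, dtype=float)
            if th.ndim != 1 or th.size < 1:
                raise ValueError("theta_profile: expected a non-empty vector")
            if th[-1] != 0.0:
                raise ValueError("theta_profile: last entry must be exactly 0")

    @property
    def n_subgroups(self) -> int:
        return len(self.true_rates)

    @property
    def n_arms(self) -> int:
        return len(self.true_rates[0])

    def rates_at_period(self, t: int, n_periods: int) -> np.ndarray:
        """True rates for analysis period ``t`` (1-based) of ``n_periods``.

        Without a drift profile the rates are constant.  With a profile of
        length ``n_periods``, period ``t`` rates are
        ``expit(logit(true_rates) + theta_profile[t-1])``.
        """
        rates = np.asarray(self.true_rates, dtype=float)
        if self.theta_profile is None:
            return rates
        th = np.asarray(self.theta_profile, dtype=float)
        if th.size != n_periods:
            raise ValueError(
                f"theta_profile has {th.size} periods but the design has {n_periods}"
            )
        if not 1 <= t <= n_periods:
            raise ValueError(f"period {t} outside 1..{n_periods}")
        return _expit(_logit(rates) + th[t - 1])

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "rates": {
                label: list(row)
                for label, row in zip(_labels_for(self.n_subgroups), self.true_rates)
            },
            "theta": None if self.theta_profile is None else list(self.theta_profile),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioSpec":
        rates_map = d["rates"]
        labels = _labels_for(len(rates_map))
        rates = tuple(tuple(float(v) for v in rates_map[label]) for label in labels)
        theta = d.get("theta")
        return cls(
            name=str(d["name"]),
            true_rates=rates,
            theta_profile=None if theta is None else tuple(float(v) for v in theta),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        return cls.from_dict(json.loads(text))


def _labels_for(J: int) -> tuple[str, ...]:
    if J == len(SUBGROUP_LABELS):
        return SUBGROUP_LABELS
    return tuple(f"Subgroup {j + 1}" for j in range(J))


class TrialData:
    """Per-(subgroup, arm, period) enrollment and favorable-outcome counts.

    ``n[j, k, t]`` participants and ``y[j, k, t]`` favorable outcomes for
    subgroup ``j``, arm ``k`` in analysis period ``t`` (0-based here).
    Outcome counts may be fractional only for the pseudo-data prior block
    (pseudo-successes are ``rate * n0``).
    """

    __slots__ = ("n", "y")

    def __init__(self, n: np.ndarray, y: np.ndarray):
        n = np.asarray(n, dtype=float)
        y = np.asarray(y, dtype=float)
        if n.shape != y.shape or n.ndim != 3:
            raise ValueError("TrialData: n and y must share a (J, K, T) shape")
        if np.any(n < 0) or np.any(y < 0) or np.any(y > n + 1e-12):
            raise ValueError("TrialData: need 0 <= y <= n in every cell")
        self.n = n
        self.y = y

    @classmethod
    def empty(cls, J: int, K: int = 2, T: int = 1) -> "TrialData":
        return cls(np.zeros((J, K, T)), np.zeros((J, K, T)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.n.shape  # type: ignore[return-value]

    @property
    def n_periods(self) -> int:
        return self.n.shape[2]

    def collapsed(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts summed over periods — the non-drift data view."""
        return self.n.sum(axis=2), self.y.sum(axis=2)

    def through_period(self, T: int) -> "TrialData":
        """Data restricted to the first ``T`` periods."""
        return TrialData(self.n[:, :, :T].copy(), self.y[:, :, :T].copy())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TrialData)
            and np.array_equal(self.n, other.n)
            and np.array_equal(self.y, other.y)
        )

    def __repr__(self) -> str:
        J, K, T = self.shape
        return f"TrialData(J={J}, K={K}, T={T}, n_total={self.n.sum():g})"
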