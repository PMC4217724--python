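"""First-order molecular-weight decay kinetics.

Hydrolytic chain scission in the early degradation phase is well
described by a first-order loss of weight-average molecular weight:
retention(t) = Mw(t)/Mw(0) = exp(−k t). The rate constant ``k``
(1/month) is fitted in log space, where the model is linear through the
origin; a single observation therefore determines ``k`` exactly,
k = −ln(retention)/t.

Separate constants are fitted per environment (in vivo vs in vitro
bench loop); in vivo degradation runs slightly faster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import DomainError, UnderdeterminedError

__all__ = [
    "MwObservation",
    "DecayModel",
    "fit_first_order",
    "predict_retention",
    "default_rate_constants",
]

#: Retentions at the 6-month follow-up used to anchor default rates.
RETENTION_6MO = {"in_vivo": 0.618, "in_vitro": 0.685}


@dataclass(frozen=True)
class MwObservation:
    """Molecular-weight retention at one follow-up time."""

    time: float  # months
    retention: float  # fraction of initial Mw, in (0, 1]
    environment: str = "in_vitro"

    def __post_init__(self):
        if self.time < 0:
            raise DomainError("time must be >= 0 months")
        if not 0.0 < self.retention <= 1.0:
            raise DomainError(f"retention must be in (0, 1], got {self.retention}")
        if self.environment not in ("in_vivo", "in_vitro"):
            raise DomainError(f"environment must be in_vivo or in_vitro, got {self.environment!r}")


@dataclass(frozen=True)
class DecayModel:
    """First-order Mw decay: retention(t) = exp(−k t), k in 1/month."""

    rate_constant: float
    environment: str = "in_vitro"

    def __post_init__(self):
        if self.rate_constant < 0 or not np.isfinite(self.rate_constant):
            raise DomainError("rate constant must be finite and >= 0")


def fit_first_order(observations: Iterable[MwObservation]) -> DecayModel:
    """Least-squares fit of k in log space.

    Minimises Σ (ln r_i + k t_i)²: k = −Σ t ln r / Σ t². Exact for a
    single observation. Observations at t = 0 carry no information
    (ln 1 = 0 expected; they still enter the sum, weightlessly since
    t = 0). All-zero times raise :class:`UnderdeterminedError`.
    """
    obs = list(observations)
    if not obs:
        raise UnderdeterminedError("no observations")
    envs = {o.environment for o in obs}
    if len(envs) > 1:
        raise DomainError("fit one environment at a time; got " + ", ".join(sorted(envs)))
    t = np.array([o.time for o in obs])
    r = np.array([o.retention for o in obs])
    if not np.any(t > 0):
        raise UnderdeterminedError("need at least one observation at time > 0")
    k = float(-np.sum(t * np.log(r)) / np.sum(t**2))
    return DecayModel(rate_constant=max(k, 0.0), environment=obs[0].environment)


def predict_retention(model: DecayModel, time) -> float:
    """retention(t) = exp(−k t); scalar or array."""
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    r = np.exp(-model.rate_constant * t)
    return float(r) if r.ndim == 0 else r


def default_rate_constants() -> dict[str, float]:
    """Rates anchored to the 6-month retentions (61.8% in vivo, 68.5% in vitro)."""
    return {env: -np.log(r) / 6.0 for env, r in RETENTION_6MO.items()}
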