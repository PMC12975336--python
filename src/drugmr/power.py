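"""Analytic power for two-sample MR with a binary outcome.

The test of the causal log-odds ratio is approximated as a normal z-test
whose non-centrality is NCP = n · r² · K(1−K) · effect², where n is the
outcome-cohort size, K the case fraction, r² the variance in the exposure
explained by the instrument, and ``effect`` the causal log-OR per SD of the
exposure.  Inverting the power curve gives the minimum detectable effect at
a target power (the familiar "detectable OR at 80% power" panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["PowerQuery", "mr_power", "detectable_effect"]


@dataclass
class PowerQuery:
    n_outcome: float
    case_fraction: float
    r2_instrument: float
    alpha: float = 0.05
    target_power: float = 0.8
    effect_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, np.log(3.0), 61)
    )

    def __post_init__(self):
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0 <= self.r2_instrument < 1:
            raise ValueError("r2_instrument must lie in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def mr_power(query: PowerQuery, effect: float) -> float:
    """Two-sided power at a causal log-OR of ``effect`` per SD of exposure.

    power = Phi(sqrt(NCP) − z_{1−α/2}) + Phi(−sqrt(NCP) − z_{1−α/2});
    at effect = 0 this equals alpha (the size of the test), and it is
    symmetric in the sign of the effect.
    """
    z_crit = stats.norm.isf(query.alpha / 2.0)
    ncp = (
        query.n_outcome
        * query.r2_instrument
        * query.case_fraction
        * (1.0 - query.case_fraction)
        * effect ** 2
    )
    root = np.sqrt(ncp)
    return float(stats.norm.cdf(root - z_crit) + stats.norm.cdf(-root - z_crit))


def detectable_effect(query: PowerQuery) -> dict:
    """Smallest |log-OR| reaching ``target_power``, found by bisection.

    Returns {"log_or": ..., "odds_ratio": ..., "feasible": bool}; with
    r² = 0 no effect is detectable and the infeasible flag is set.
    """
    if not query.alpha < query.target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    if query.r2_instrument == 0:
        return {"log_or": np.inf, "odds_ratio": np.inf, "feasible": False}

    def gap(e):
        return mr_power(query, e) - query.target_power

    hi = 1.0
    while gap(hi) < 0 and hi < 1e6:
        hi *= 2.0
    if gap(hi) < 0:
        return {"log_or": np.inf, "odds_ratio": np.inf, "feasible": False}
    effect = optimize.brentq(gap, 0.0, hi, xtol=1e-6)
    return {"log_or": float(effect), "odds_ratio": float(np.exp(effect)),
            "feasible": True}
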