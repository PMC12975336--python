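"""Cross-ancestry meta-analysis, mediation and grouped FDR control.

Fixed-effect inverse-variance meta-analysis pools per-ancestry MR estimates
(log-odds scale for binary outcomes).  Mediation uses the product of
coefficients with the exact-variance standard error
sqrt(alpha²·se_beta² + beta²·se_alpha² − se_alpha²·se_beta²); near
alpha = beta = 0 the operand of that unbiased variance estimator can go
negative, in which case the first-order delta-method SE is substituted and
flagged.  FDR control is Benjamini–Hochberg applied independently within
feature families (e.g. per microbial taxonomic rank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import Z95

__all__ = [
    "MetaResult",
    "MediationResult",
    "fixed_effect_meta",
    "ci_to_se",
    "or_ci_to_estimate",
    "mediation_product",
    "bh_fdr",
]


@dataclass
class MetaResult:
    theta: float
    se: float
    thetas: list[float]
    ses: list[float]
    q_meta: float
    i_squared: float

    @property
    def ci_low(self) -> float:
        return self.theta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + Z95 * self.se

    @property
    def pvalue(self) -> float:
        return 2.0 * stats.norm.sf(abs(self.theta) / self.se)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    @property
    def q_pvalue(self) -> float:
        df = len(self.thetas) - 1
        return 1.0 if df <= 0 else float(stats.chi2.sf(self.q_meta, df))


@dataclass
class MediationResult:
    alpha: float
    se_alpha: float
    beta: float
    se_beta: float
    total: float
    se_total: float
    se_fallback_used: bool = False

    @property
    def indirect(self) -> float:
        return self.alpha * self.beta

    @property
    def se_indirect(self) -> float:
        operand = (
            self.alpha ** 2 * self.se_beta ** 2
            + self.beta ** 2 * self.se_alpha ** 2
            - self.se_alpha ** 2 * self.se_beta ** 2
        )
        if operand < 0:
            return math.sqrt(
                self.alpha ** 2 * self.se_beta ** 2
                + self.beta ** 2 * self.se_alpha ** 2
            )
        return math.sqrt(operand)

    @property
    def indirect_pvalue(self) -> float:
        se = self.se_indirect
        if se == 0:
            return 1.0 if self.indirect == 0 else 0.0
        return 2.0 * stats.norm.sf(abs(self.indirect) / se)

    @property
    def proportion_mediated(self) -> float | None:
        """Indirect / total, as a percentage; None when total ≈ 0."""
        if abs(self.total) < 1e-12:
            return None
        return 100.0 * self.indirect / self.total


def fixed_effect_meta(estimates) -> MetaResult:
    """Inverse-variance fixed-effect pooling of (theta, se) pairs.

    I² = max(0, (Q − df) / Q) summarises between-study heterogeneity; the
    pooled SE is (Σ se_i⁻²)^−1/2.
    """
    pairs = [(float(t), float(s)) for t, s in estimates]
    if not pairs:
        raise ValueError("fixed_effect_meta needs at least one estimate")
    if any(s <= 0 for _, s in pairs):
        raise ValueError("all standard errors must be positive")
    thetas = np.array([t for t, _ in pairs])
    ses = np.array([s for _, s in pairs])
    w = ses ** -2.0
    theta = float((w * thetas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    q = float((w * (thetas - theta) ** 2).sum())
    df = len(pairs) - 1
    i2 = 0.0 if q <= 0 or df <= 0 else max(0.0, (q - df) / q)
    return MetaResult(theta=theta, se=se, thetas=list(thetas), ses=list(ses),
                      q_meta=q, i_squared=i2)


def ci_to_se(low: float, high: float) -> float:
    """SE implied by a symmetric 95% interval: (high − low) / (2·1.959964)."""
    if not high > low:
        raise ValueError(f"need high > low, got [{low}, {high}]")
    return (high - low) / (2.0 * Z95)


def or_ci_to_estimate(odds_ratio: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """(log-OR, SE) reconstructed from a printed OR with its 95% CI."""
    if not (0 < ci_low < ci_high):
        raise ValueError("need 0 < ci_low < ci_high")
    return math.log(odds_ratio), ci_to_se(math.log(ci_low), math.log(ci_high))


def mediation_product(
    alpha: float,
    se_alpha: float,
    beta: float,
    se_beta: float,
    total: float,
    se_total: float,
) -> MediationResult:
    """Product-of-coefficients mediation through a single mediator.

    ``alpha`` is the exposure→mediator effect, ``beta`` the
    mediator→outcome effect adjusted for the exposure, and ``total`` the
    total exposure→outcome effect from univariable MR (the denominator of
    the proportion mediated).
    """
    for name, se in (("se_alpha", se_alpha), ("se_beta", se_beta),
                     ("se_total", se_total)):
        if not se > 0:
            raise ValueError(f"{name} must be positive, got {se}")
    operand = alpha ** 2 * se_beta ** 2 + beta ** 2 * se_alpha ** 2 \
        - se_alpha ** 2 * se_beta ** 2
    return MediationResult(
        alpha=alpha, se_alpha=se_alpha, beta=beta, se_beta=se_beta,
        total=total, se_total=se_total, se_fallback_used=operand < 0,
    )


def bh_fdr(pvalues, groups=None) -> np.ndarray:
    """Benjamini–Hochberg q-values, computed independently within groups.

    ``groups`` assigns each p-value to a feature family (e.g. a microbial
    taxonomic rank); None puts everything in one family.  Q-values are
    monotone step-up within each family.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if groups is None:
        groups = np.zeros(p.size)
    groups = np.asarray(groups)
    if groups.shape != p.shape:
        raise ValueError("groups must align with pvalues")
    q = np.empty_like(p)
    for g in np.unique(groups):
        mask = groups == g
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q
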