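"""Two-sample MR estimators for correlated instruments.

All multi-instrument estimators are generalized-least-squares fits with the
outcome covariance Omega_ij = se_y_i * se_y_j * rho_ij, where rho is the LD
correlation between instruments (the NOME convention: exposure-side
uncertainty does not enter the weights).  With identity LD they reduce to
the textbook inverse-variance-weighted forms.

Estimates are returned on the scale of the inputs: per unit (or per SD) of
the exposure for quantitative outcomes, log-odds for binary outcomes; odds
ratios are an exp-transform applied at the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    InsufficientInstrumentsError,
    NumericalError,
)
from .ld import InstrumentSet, condition_psd

__all__ = [
    "MREstimate",
    "Z95",
    "wald_ratio",
    "ivw_correlated",
    "mr_egger_correlated",
    "cochran_q",
    "mvmr_correlated",
]

#: two-sided 95% normal quantile, fixed across the package
Z95 = 1.959964


@dataclass
class MREstimate:
    """A causal-effect estimate with provenance."""

    method: str
    theta: float
    se: float
    n_snps: int
    model: str = "fixed"
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None

    @property
    def ci_low(self) -> float:
        return self.theta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.theta + Z95 * self.se

    @property
    def pvalue(self) -> float:
        if self.se == 0:
            return 0.0 if self.theta != 0 else 1.0
        return 2.0 * stats.norm.sf(abs(self.theta) / self.se)

    @property
    def odds_ratio(self) -> float:
        """exp(theta); meaningful when theta is a log-odds ratio."""
        return float(np.exp(self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "exposure": self.exposure_id,
            "outcome": self.outcome_id,
            "model": self.model,
            "n_snps": self.n_snps,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "q_stat": self.q_stat,
            "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
        }


def wald_ratio(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-instrument causal estimate beta_y / beta_x.

    The default SE is first order, ``se_y / |beta_x|``; ``second_order``
    adds the exposure-uncertainty term of the delta method,
    ``sqrt(se_y²/beta_x² + beta_y²·se_x²/beta_x⁴)``, which is never smaller.
    """
    if beta_x == 0:
        raise ZeroDivisionError("wald ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    if second_order:
        se = np.sqrt(se_y ** 2 / beta_x ** 2 + beta_y ** 2 * se_x ** 2 / beta_x ** 4)
    else:
        se = se_y / abs(beta_x)
    return MREstimate(method="wald", theta=float(theta), se=float(se), n_snps=1)


def _omega(instruments: InstrumentSet) -> np.ndarray:
    """Outcome covariance D rho D, PSD-conditioned."""
    d = instruments.se_y
    rho = condition_psd(instruments.ld.r)
    return rho * np.outer(d, d)


def _solve(omega: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(omega, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - conditioned upstream
        raise NumericalError(
            f"singular weight matrix (cond={np.linalg.cond(omega):.3g}, "
            f"shape={omega.shape})"
        ) from exc


def cochran_q(instruments: InstrumentSet, theta: float) -> tuple[float, float]:
    """Generalized heterogeneity statistic at a given causal effect.

    Q = (beta_y − theta·beta_x)' Omega⁻¹ (beta_y − theta·beta_x), referred to
    a chi-square with n_snps − 1 degrees of freedom.  With identity LD this
    is the familiar sum of squared residual z-scores.
    """
    if instruments.n_snps < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    bx = instruments.beta_x[:, 0]
    resid = instruments.beta_y - theta * bx
    q = float(resid @ _solve(_omega(instruments), resid))
    df = instruments.n_snps - 1
    return q, float(stats.chi2.sf(q, df))


def ivw_correlated(
    instruments: InstrumentSet,
    model: str | None = None,
) -> MREstimate:
    """Inverse-variance-weighted estimate accounting for instrument LD.

    theta = (x' Omega⁻¹ y) / (x' Omega⁻¹ x), se_fixed = (x' Omega⁻¹ x)^-1/2.
    ``model`` is "fixed" or "multiplicative_random"; when None, fixed is used
    for up to 3 instruments and multiplicative-random above that, and the
    random-effects SE is the fixed SE inflated by max(1, sqrt(Q/(n−1))).
    A single instrument reduces exactly to the Wald ratio.
    """
    m = instruments.n_snps
    if m < 1:
        raise InsufficientInstrumentsError("IVW needs >= 1 instrument")
    if instruments.n_exposures != 1:
        raise ValueError("ivw_correlated is univariable; use mvmr_correlated")
    if model is None:
        model = "fixed" if m <= 3 else "multiplicative_random"
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown model {model!r}")

    bx = instruments.beta_x[:, 0]
    by = instruments.beta_y
    omega = _omega(instruments)
    wx = _solve(omega, bx)
    denom = float(bx @ wx)
    if denom <= 0:
        raise NumericalError("x' Omega^-1 x is not positive")
    theta = float(bx @ _solve(omega, by)) / denom
    se = denom ** -0.5

    q_stat = q_p = None
    if m >= 2:
        q_stat, q_p = cochran_q(instruments, theta)
        if model == "multiplicative_random":
            se *= max(1.0, np.sqrt(q_stat / (m - 1)))
    est = MREstimate(
        method="ivw_correlated", theta=theta, se=float(se), n_snps=m,
        model=model, q_stat=q_stat, q_pvalue=q_p,
        exposure_id=instruments.exposure_ids[0],
        outcome_id=instruments.outcome_id,
    )
    return est


def mr_egger_correlated(instruments: InstrumentSet) -> MREstimate:
    """MR-Egger regression under instrument correlation.

    Each instrument is oriented so its exposure effect is non-negative (the
    outcome effect and the corresponding LD signs are co-flipped), then
    beta_y is GLS-regressed on (1, beta_x).  The slope is the causal
    estimate; a nonzero intercept indicates directional pleiotropy.
    """
    m = instruments.n_snps
    if m < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    if instruments.n_exposures != 1:
        raise ValueError("mr_egger_correlated is univariable")

    bx = instruments.beta_x[:, 0].copy()
    by = instruments.beta_y.copy()
    signs = np.where(bx < 0, -1.0, 1.0)
    bx *= signs
    by *= signs
    rho = condition_psd(instruments.ld.r * np.outer(signs, signs))
    omega = rho * np.outer(instruments.se_y, instruments.se_y)

    X = np.column_stack([np.ones(m), bx])
    wX = _solve(omega, X)
    info = X.T @ wX
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("Egger design is singular (constant beta_x?)") from exc
    coef = cov @ (wX.T @ by)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    resid = by - X @ coef
    q = float(resid @ _solve(omega, resid))
    q_p = float(stats.chi2.sf(q, m - 2)) if m > 2 else None
    return MREstimate(
        method="egger", theta=slope, se=se_slope, n_snps=m, model="fixed",
        q_stat=q, q_pvalue=q_p,
        egger_intercept=intercept, egger_intercept_se=se_int,
        egger_intercept_pvalue=2.0 * stats.norm.sf(abs(intercept) / se_int),
        exposure_id=instruments.exposure_ids[0],
        outcome_id=instruments.outcome_id,
    )


def mvmr_correlated(instruments: InstrumentSet) -> list[MREstimate]:
    """Multivariable MR: joint GLS of beta_y on all exposure columns.

    theta = (Bx' Omega⁻¹ Bx)⁻¹ Bx' Omega⁻¹ beta_y, with per-exposure SEs
    from the diagonal of the inverse information.  With one exposure this is
    exactly :func:`ivw_correlated` (fixed model).
    """
    m, k = instruments.n_snps, instruments.n_exposures
    if m < k:
        raise InsufficientInstrumentsError(
            f"MVMR with {k} exposures needs >= {k} instruments, got {m}"
        )
    Bx = instruments.beta_x
    s = np.linalg.svd(Bx, compute_uv=False)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        raise CollinearityError(
            f"exposure design is rank deficient (singular values {s})"
        )
    omega = _omega(instruments)
    wB = _solve(omega, Bx)
    info = Bx.T @ wB
    cov = np.linalg.inv(info)
    theta = cov @ (wB.T @ instruments.beta_y)
    resid = instruments.beta_y - Bx @ theta
    q = float(resid @ _solve(omega, resid)) if m > k else None
    q_p = float(stats.chi2.sf(q, m - k)) if q is not None else None
    return [
        MREstimate(
            method="mvmr", theta=float(theta[j]), se=float(np.sqrt(cov[j, j])),
            n_snps=m, model="fixed", q_stat=q, q_pvalue=q_p,
            exposure_id=instruments.exposure_ids[j]
            if j < len(instruments.exposure_ids) else f"exposure_{j}",
            outcome_id=instruments.outcome_id,
        )
        for j in range(k)
    ]
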