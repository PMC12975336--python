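"""Summary-data-based MR (SMR), multi-SNP SMR, HEIDI and GSMR.

SMR tests whether a molecular trait (e.g. a protein, via its top cis-QTL)
and a disease share an association signal; HEIDI asks whether a *single*
causal variant can explain both traits' associations across the region
(small p = linkage, not pleiotropy/causality).  GSMR is a multi-instrument
estimator with iterative heterogeneity-outlier removal, used here for
reverse MR of disease liability on molecular traits.

Weighted-chi-square null distributions (multi-SNP SMR, HEIDI) are evaluated
by two-moment Satterthwaite matching: T ~ c·chi2(nu) with c = sum(l²)/sum(l)
and nu = (sum l)²/sum(l²) over the eigenvalues l of the relevant correlation
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, NoInstrumentsError
from .estimators import MREstimate, ivw_correlated
from .ld import InstrumentSet
from .sumstats import Variant

__all__ = [
    "SMRResult",
    "smr_test",
    "smr_multi",
    "heidi_test",
    "gsmr_estimate",
    "satterthwaite_pvalue",
]

#: default QTL p-value ceiling for HEIDI SNP eligibility (~z > 3.16)
HEIDI_QTL_P_MAX = 1.57e-3


def satterthwaite_pvalue(t: float, weights: np.ndarray) -> float:
    """Tail probability of sum_k w_k * chi2_1 at ``t`` by moment matching."""
    w = np.asarray(weights, dtype=float)
    w = w[w > 1e-12]
    if w.size == 0:
        return 1.0
    s1, s2 = w.sum(), (w ** 2).sum()
    scale = s2 / s1
    df = s1 ** 2 / s2
    return float(stats.chi2.sf(t / scale, df))


@dataclass
class SMRResult:
    b_smr: float
    se_smr: float
    p_smr: float
    p_smr_multi: float | None
    p_heidi: float | None
    n_heidi_snps: int
    top_variant: Variant | None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.b_smr))


def smr_test(z_x: float, z_y: float, beta_x: float, beta_y: float
             ) -> tuple[float, float]:
    """Single-QTL SMR test.

    b_smr = beta_y/beta_x; the test statistic T = z_x²·z_y²/(z_x² + z_y²)
    is referred to chi-square with 1 df.  Returns (b_smr, p_smr).
    """
    if z_x == 0:
        raise ValueError("smr_test requires a nonzero exposure z-score")
    if beta_x == 0:
        raise ValueError("smr_test requires a nonzero exposure beta")
    b = beta_y / beta_x
    zx2, zy2 = z_x ** 2, z_y ** 2
    t = zx2 * zy2 / (zx2 + zy2)
    return float(b), float(stats.chi2.sf(t, 1))


def _smr_stats(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    zx = instruments.beta_x[:, 0] / instruments.se_x[:, 0]
    zy = instruments.beta_y / instruments.se_y
    t = np.where(
        (zx ** 2 + zy ** 2) > 0, zx ** 2 * zy ** 2 / (zx ** 2 + zy ** 2), 0.0
    )
    return zx, zy, t


def smr_multi(
    instruments: InstrumentSet,
    p_qtl_threshold: float = 5e-8,
    max_snps: int = 10,
) -> float:
    """Multi-SNP SMR p-value.

    Sums the per-SNP SMR statistics over the ``max_snps`` strongest QTLs
    passing ``p_qtl_threshold``; the null is a weighted sum of 1-df
    chi-squares whose weights are the eigenvalues of the LD correlation of
    the selected SNPs (so a duplicated SNP contributes ~1 effective df,
    independent SNPs contribute one each).
    """
    zx, zy, t = _smr_stats(instruments)
    p_qtl = 2.0 * stats.norm.sf(np.abs(zx))
    sel = np.flatnonzero(p_qtl < p_qtl_threshold)
    if sel.size == 0:
        raise NoInstrumentsError(
            f"no QTL passes p < {p_qtl_threshold} for multi-SNP SMR"
        )
    if sel.size > max_snps:
        sel = sel[np.argsort(p_qtl[sel], kind="stable")][:max_snps]
    if sel.size == 1:
        i = int(sel[0])
        return float(stats.chi2.sf(t[i], 1))
    rho = instruments.ld.r[np.ix_(sel, sel)]
    eig = np.linalg.eigvalsh((rho + rho.T) / 2.0)
    return satterthwaite_pvalue(float(t[sel].sum()), np.clip(eig, 0.0, None))


def heidi_test(
    instruments: InstrumentSet,
    top_variant: Variant | None = None,
    qtl_p_max: float = HEIDI_QTL_P_MAX,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
) -> tuple[float | None, int]:
    """HEIDI: heterogeneity in dependent instruments.

    Per eligible SNP i the deviation d_i = b_i − b_top of its Wald ratio from
    the top QTL's is formed; under a single shared causal variant every d_i
    is zero in expectation.  T = sum d_i²/var(d_i) is referred to a weighted
    chi-square via the correlation of the standardized deviations.

    Variances follow the delta method, with LD entering both trait sides:
    var(b_i) = se_y_i²/bx_i² + b_top²·se_x_i²/bx_i², and
    cov(b_i, b_j) = rho_ij·(se_y_i·se_y_j + b_top²·se_x_i·se_x_j)/(bx_i·bx_j).

    Eligible SNPs have QTL p < ``qtl_p_max`` and r² with the top SNP inside
    ``r2_window``, capped at the ``max_snps`` strongest.  Returns
    (p_heidi, n_used); p is None (test undefined) when nothing is eligible.
    """
    zx, zy, _ = _smr_stats(instruments)
    if top_variant is None:
        top = int(np.argmax(np.abs(zx)))
    else:
        top = instruments.ld.index_of(top_variant)
    p_qtl = 2.0 * stats.norm.sf(np.abs(zx))
    r2_top = instruments.ld.r[top] ** 2
    lo, hi = r2_window
    eligible = np.flatnonzero(
        (np.arange(instruments.n_snps) != top)
        & (p_qtl < qtl_p_max)
        & (r2_top >= lo)
        & (r2_top <= hi)
    )
    if eligible.size == 0:
        return None, 0
    if eligible.size > max_snps:
        eligible = eligible[np.argsort(p_qtl[eligible], kind="stable")][:max_snps]
    eligible = np.sort(eligible)

    idx = np.concatenate([[top], eligible])
    bx = instruments.beta_x[idx, 0]
    sx = instruments.se_x[idx, 0]
    by = instruments.beta_y[idx]
    sy = instruments.se_y[idx]
    rho = instruments.ld.r[np.ix_(idx, idx)]
    b = by / bx
    b_top = b[0]

    # cov(b_i, b_j) over the whole selected block, top included at index 0
    cov_b = rho * (np.outer(sy, sy) + b_top ** 2 * np.outer(sx, sx)) \
        / np.outer(bx, bx)
    k = eligible.size
    cov_d = (
        cov_b[1:, 1:]
        - cov_b[1:, [0]]
        - cov_b[[0], 1:]
        + cov_b[0, 0]
    )
    d = b[1:] - b_top
    var_d = np.diag(cov_d).copy()
    var_d[var_d <= 0] = np.finfo(float).tiny
    t = float((d ** 2 / var_d).sum())
    sd = np.sqrt(var_d)
    corr_d = cov_d / np.outer(sd, sd)
    corr_d = np.clip((corr_d + corr_d.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr_d, 1.0)
    eig = np.clip(np.linalg.eigvalsh(corr_d), 0.0, None)
    return satterthwaite_pvalue(t, eig), int(k)


def gsmr_estimate(
    instruments: InstrumentSet,
    outlier_p: float = 0.01,
    model: str = "fixed",
) -> MREstimate:
    """GSMR-style estimate: correlated IVW with HEIDI-outlier removal.

    Iteratively drops the instrument whose single-SNP Wald ratio deviates
    most from the pooled estimate when that deviation is significant at
    ``outlier_p`` (chi-square, 1 df, delta-method variance including the
    exposure side), then re-estimates.  With ``outlier_p = 0`` no instrument
    is ever removed and the result equals plain correlated IVW.
    """
    if instruments.n_snps < 1:
        raise NoInstrumentsError("gsmr needs >= 1 instrument")
    current = instruments
    while True:
        est = ivw_correlated(current, model=model)
        if current.n_snps <= 1:
            break
        bx = current.beta_x[:, 0]
        sx = current.se_x[:, 0]
        b = current.beta_y / bx
        var_b = current.se_y ** 2 / bx ** 2 + est.theta ** 2 * sx ** 2 / bx ** 2
        chi = (b - est.theta) ** 2 / var_b
        p = stats.chi2.sf(chi, 1)
        worst = int(np.argmax(chi))
        if p[worst] >= outlier_p:
            break
        keep = [i for i in range(current.n_snps) if i != worst]
        if not keep:
            raise NoInstrumentsError("gsmr outlier filtering removed everything")
        current = current.subset(keep)
    est.method = "gsmr"
    return est
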