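"""Synthetic two-sample GWAS generator with known ground truth.

The generator emulates the statistical structure of a drug-target MR study:
an LD block containing a drug-target gene region, a heritable quantitative
exposure (LDL-C-like, unit variance), optional molecular mediators on the
exposure→outcome path, and an outcome that is either quantitative or a
binary liability trait (T2D-like) dichotomized at a prevalence quantile.

Genotypes come from a latent multivariate-normal threshold model: each
haplotype draws a correlated Gaussian vector and carries the alternate
allele wherever the draw falls below the allele-frequency quantile, so
dosages are Hardy–Weinberg consistent and neighbouring variants are
correlated (the realized dosage correlation is mildly attenuated relative to
the latent target — the same LD enters the analysis via the simulated
reference panel, so estimators see a self-consistent system).

Exposure, mediator and outcome cohorts are disjoint by construction (the
two/three-sample assumption).  A master seed fans out to named substreams so
each stage is independently reproducible.

``sample_marginal_stats`` is the fast companion path: it draws marginal
effect estimates directly from their asymptotic sampling distribution
beta_hat ~ N(rho·gamma, sigma²·rho/n) on the standardized-genotype scale,
which is what large replicate calibration suites use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import stats

from .errors import ConfigError
from .ld import InstrumentSet, LDMatrix, condition_psd, ld_from_genotypes
from .sumstats import AssociationRecord, SummaryDataset, Variant

__all__ = [
    "MediatorSpec",
    "SimConfig",
    "TruthManifest",
    "SimulatedStudy",
    "build_ld_target",
    "simulate_genotypes",
    "simulate_two_sample_study",
    "simulate_coloc_scenario",
    "sample_marginal_stats",
    "instrument_set_from_arrays",
    "dataset_from_arrays",
]


@dataclass(frozen=True)
class MediatorSpec:
    """A molecular mediator on the exposure→outcome path.

    ``alpha_true`` is the effect of the exposure on the mediator,
    ``beta_true`` the direct effect of the mediator on the outcome, and
    ``causal`` lists (variant index, effect) pairs giving the mediator its
    own genetic determinants (needed for multivariable identification).
    """

    name: str
    alpha_true: float
    beta_true: float
    causal: tuple = ()


def _default_causal() -> tuple:
    # 10 causal variants spread across the block, equal effects
    return tuple((j, 0.12) for j in range(2, 50, 5))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the package's reference scenario."""

    n_variants: int = 50
    ld_model: tuple = ("ar1", 0.7)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    n_mediator: int = 20_000
    n_ref: int = 500
    causal: tuple = field(default_factory=_default_causal)
    theta_true: float = 0.35
    mediators: tuple = ()
    outcome_type: Literal["quantitative", "binary"] = "quantitative"
    prevalence: float = 0.1
    binary_engine: Literal["logistic", "linear"] = "logistic"
    chrom: str = "5"
    region_tss: int = 75_336_161
    region_span: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 < self.prevalence < 1:
            raise ConfigError("prevalence must lie in (0, 1)")
        for j, _ in self.causal:
            if not 0 <= j < self.n_variants:
                raise ConfigError(f"causal index {j} outside variant range")


@dataclass
class TruthManifest:
    """Ground truth serialized alongside every simulated dataset."""

    config: dict
    maf: list
    gamma: list                # per-variant joint effects on the exposure
    beta_marginal_x: list      # rho @ gamma on the standardized scale
    exposure_sd: float         # realized SD of the exposure in its cohort
    theta_direct: float
    theta_total: float         # direct + sum(alpha·beta) over mediators
    mediators: dict            # name -> {alpha, beta, proportion_pct}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedStudy:
    exposure: SummaryDataset
    outcome: SummaryDataset
    mediators: dict
    ld: LDMatrix
    truth: TruthManifest
    variants: list


# ---------------------------------------------------------------------------
# LD targets and genotypes


def build_ld_target(n_variants: int, ld_model: tuple) -> np.ndarray:
    """Target latent correlation matrix: ar1(rho) or block(sizes, rho)."""
    kind = ld_model[0]
    if kind == "ar1":
        rho = float(ld_model[1])
        if not -1 < rho < 1:
            raise ConfigError("ar1 rho must lie in (-1, 1)")
        idx = np.arange(n_variants)
        return rho ** np.abs(np.subtract.outer(idx, idx))
    if kind == "block":
        sizes, rho = list(ld_model[1]), float(ld_model[2])
        if sum(sizes) != n_variants:
            raise ConfigError("block sizes must sum to n_variants")
        r = np.eye(n_variants)
        start = 0
        for s in sizes:
            r[start:start + s, start:start + s] = rho
            start += s
        np.fill_diagonal(r, 1.0)
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ConfigError("block LD target is not positive semi-definite")
        return r
    raise ConfigError(f"unknown ld_model kind {kind!r}")


def _region_variants(config: SimConfig, maf: np.ndarray) -> list[Variant]:
    start = config.region_tss - config.region_span // 2
    spacing = max(config.region_span // max(config.n_variants, 1), 1)
    return [
        Variant(config.chrom, start + j * spacing,
                f"{config.chrom}:{start + j * spacing}",
                "A", "G", eaf=float(maf[j]))
        for j in range(config.n_variants)
    ]


def _draw_maf(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_variants)


def simulate_genotypes(
    config: SimConfig,
    n_samples: int,
    maf: np.ndarray,
    chol: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (n_samples, n_variants) dosages from the threshold model."""
    m = config.n_variants
    thresholds = stats.norm.ppf(maf)
    z = rng.standard_normal((2 * n_samples, m)) @ chol.T
    alleles = (z < thresholds).astype(np.float64)
    return alleles[0::2] + alleles[1::2]


def _standardize(g: np.ndarray) -> np.ndarray:
    mu = g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return (g - mu) / sd


def _marginal_quantitative(g: np.ndarray, y: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-variant simple OLS (with intercept) of y on dosage."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    sxy = gc.T @ yc
    beta = sxy / sxx
    rss = (yc ** 2).sum() - beta * sxy
    se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
    return beta, se


def _marginal_logistic(g: np.ndarray, y: np.ndarray, n_iter: int = 12
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-variant logistic regression (intercept + dosage).

    Newton–Raphson run simultaneously for every variant; adequate for the
    well-behaved dosage predictors the generator produces.
    """
    n, m = g.shape
    k = y.mean()
    a = np.full(m, np.log(k / (1 - k)))
    b = np.zeros(m)
    yv = y[:, None]
    for _ in range(n_iter):
        eta = a[None, :] + g * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = yv - p
        g0 = r.sum(axis=0)
        g1 = (r * g).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * g).sum(axis=0)
        h11 = (w * g * g).sum(axis=0)
        det = h00 * h11 - h01 ** 2
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-10:
            break
    eta = a[None, :] + g * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    h00 = w.sum(axis=0)
    h01 = (w * g).sum(axis=0)
    h11 = (w * g * g).sum(axis=0)
    det = h00 * h11 - h01 ** 2
    se = np.sqrt(h00 / det)
    return b, se


def _marginal_linear_probability(g: np.ndarray, y: np.ndarray
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Linear-probability shortcut rescaled to the log-odds scale."""
    beta, se = _marginal_quantitative(g, y)
    k = y.mean()
    scale = 1.0 / (k * (1.0 - k))
    return beta * scale, se * scale


def dataset_from_arrays(
    variants: list[Variant],
    beta: np.ndarray,
    se: np.ndarray,
    n: float,
    trait_id: str,
    trait_type: str = "quantitative",
    ancestry: str = "other",
) -> SummaryDataset:
    """Wrap effect/SE vectors into a SummaryDataset (p from |beta/se|)."""
    pvals = np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), 1e-320, 1.0)
    ds = SummaryDataset(trait_id=trait_id, trait_type=trait_type,
                        ancestry=ancestry)
    for v, b, s, p in zip(variants, beta, se, pvals):
        ds.add(AssociationRecord(
            variant=v, beta=float(b), se=float(s), pvalue=float(p), n=n,
            trait_id=trait_id, ancestry=ancestry,
        ))
    return ds


def _effect_vector(n_variants: int, causal) -> np.ndarray:
    gamma = np.zeros(n_variants)
    for j, g in causal:
        gamma[j] += g
    return gamma


def simulate_two_sample_study(config: SimConfig) -> SimulatedStudy:
    """Full individual-level simulation of a two/three-sample MR study.

    Produces exposure, outcome and per-mediator summary datasets from
    disjoint cohorts, an LD matrix estimated from a separate reference
    panel, and the ground-truth manifest.
    """
    master = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ["maf", "ref", "exposure", "outcome", "mediator"],
            master.spawn(5),
        )
    }
    maf = _draw_maf(config, streams["maf"])
    variants = _region_variants(config, maf)
    rho_target = build_ld_target(config.n_variants, config.ld_model)
    chol = np.linalg.cholesky(condition_psd(rho_target))
    gamma = _effect_vector(config.n_variants, config.causal)

    # reference panel -> LD matrix used by every estimator
    g_ref = simulate_genotypes(config, config.n_ref, maf, chol, streams["ref"])
    ld = ld_from_genotypes(g_ref.T, variants)
    if ld.n_variants != config.n_variants:
        raise ConfigError("reference panel produced monomorphic variants; "
                          "increase n_ref or the minimum MAF")

    def make_phenotypes(g: np.ndarray, rng: np.random.Generator):
        gs = _standardize(g)
        x_gen = gs @ gamma
        x = x_gen + rng.standard_normal(g.shape[0]) * max(
            np.sqrt(max(1.0 - float(gamma @ rho_target @ gamma), 1e-6)), 1e-3
        )
        meds = {}
        for spec in config.mediators:
            delta = _effect_vector(config.n_variants, spec.causal)
            meds[spec.name] = (
                spec.alpha_true * x + gs @ delta
                + rng.standard_normal(g.shape[0])
            )
        return x, meds

    # exposure cohort
    g_x = simulate_genotypes(config, config.n_exposure, maf, chol,
                             streams["exposure"])
    x, _ = make_phenotypes(g_x, streams["exposure"])
    beta_x, se_x = _marginal_quantitative(g_x, x)
    exposure_sd = float(x.std())
    exposure = dataset_from_arrays(variants, beta_x, se_x, config.n_exposure,
                                   "exposure", "quantitative")

    # mediator cohort(s) — one shared disjoint cohort
    mediator_ds = {}
    if config.mediators:
        g_m = simulate_genotypes(config, config.n_mediator, maf, chol,
                                 streams["mediator"])
        _, meds = make_phenotypes(g_m, streams["mediator"])
        for name, mvals in meds.items():
            bm, sm = _marginal_quantitative(g_m, mvals)
            mediator_ds[name] = dataset_from_arrays(
                variants, bm, sm, config.n_mediator, name, "quantitative"
            )

    # outcome cohort
    g_y = simulate_genotypes(config, config.n_outcome, maf, chol,
                             streams["outcome"])
    x_y, meds_y = make_phenotypes(g_y, streams["outcome"])
    liability = config.theta_true * x_y + streams["outcome"].standard_normal(
        config.n_outcome
    )
    for spec in config.mediators:
        liability = liability + spec.beta_true * meds_y[spec.name]
    if config.outcome_type == "binary":
        cut = np.quantile(liability, 1.0 - config.prevalence)
        y = (liability > cut).astype(float)
        if config.binary_engine == "logistic":
            beta_y, se_y = _marginal_logistic(g_y, y)
        else:
            beta_y, se_y = _marginal_linear_probability(g_y, y)
    else:
        y = liability
        beta_y, se_y = _marginal_quantitative(g_y, y)
    outcome = dataset_from_arrays(variants, beta_y, se_y, config.n_outcome,
                                  "outcome", config.outcome_type)

    theta_total = config.theta_true + sum(
        s.alpha_true * s.beta_true for s in config.mediators
    )
    truth = TruthManifest(
        config={**asdict(config),
                "ld_model": list(config.ld_model),
                "causal": [list(c) for c in config.causal],
                "mediators": [asdict(s) for s in config.mediators]},
        maf=[float(f) for f in maf],
        gamma=[float(g) for g in gamma],
        beta_marginal_x=[float(b) for b in rho_target @ gamma],
        exposure_sd=exposure_sd,
        theta_direct=config.theta_true,
        theta_total=theta_total,
        mediators={
            s.name: {
                "alpha": s.alpha_true,
                "beta": s.beta_true,
                "proportion_pct": 100.0 * s.alpha_true * s.beta_true
                / theta_total if theta_total else None,
            }
            for s in config.mediators
        },
    )
    return SimulatedStudy(
        exposure=exposure, outcome=outcome, mediators=mediator_ds,
        ld=ld, truth=truth, variants=variants,
    )


# ---------------------------------------------------------------------------
# fast summary-level sampling


def sample_marginal_stats(
    beta_marginal: np.ndarray,
    ld: np.ndarray,
    n: float,
    rng: np.random.Generator,
    sigma: float = 1.0,
    chol: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample marginal GWAS estimates from their asymptotic distribution.

    On the standardized-genotype scale, beta_hat ~ N(beta_marginal,
    sigma²·rho/n) and every SE is sigma/sqrt(n).  Pass a pre-computed
    Cholesky factor of the (PSD-conditioned) LD matrix to amortize it across
    replicates.
    """
    beta_marginal = np.asarray(beta_marginal, dtype=float)
    if chol is None:
        chol = np.linalg.cholesky(condition_psd(np.asarray(ld, dtype=float)))
    noise = chol @ rng.standard_normal(beta_marginal.size)
    beta_hat = beta_marginal + sigma / np.sqrt(n) * noise
    se = np.full(beta_marginal.size, sigma / np.sqrt(n))
    return beta_hat, se


def instrument_set_from_arrays(
    beta_x: np.ndarray,
    se_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    ld: np.ndarray | LDMatrix,
    variants: list[Variant] | None = None,
    exposure_ids: list[str] | None = None,
    outcome_id: str = "outcome",
) -> InstrumentSet:
    """Assemble an InstrumentSet directly from simulated arrays."""
    beta_y = np.asarray(beta_y, dtype=float)
    m = beta_y.size
    if variants is None:
        variants = [Variant("1", j + 1, f"1:{j + 1}", "A", "G")
                    for j in range(m)]
    if isinstance(ld, LDMatrix):
        ldm = ld
    else:
        ldm = LDMatrix(variants, condition_psd(np.asarray(ld, dtype=float)))
    return InstrumentSet(
        variants=variants,
        beta_x=np.asarray(beta_x, dtype=float),
        se_x=np.asarray(se_x, dtype=float),
        beta_y=beta_y,
        se_y=np.asarray(se_y, dtype=float),
        ld=ldm,
        exposure_ids=exposure_ids or ["exposure"],
        outcome_id=outcome_id,
    )


def simulate_coloc_scenario(
    scenario: Literal["shared", "distinct", "null"],
    n_variants: int = 100,
    ld_rho: float = 0.8,
    explained_variance: float = 0.01,
    n1: float = 20_000,
    n2: float = 20_000,
    distinct_r2_bound: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> tuple[SummaryDataset, SummaryDataset, dict]:
    """Region summary statistics for the three colocalization scenarios.

    shared: one causal variant drives both traits; distinct: each trait has
    its own causal variant, with pairwise r² below ``distinct_r2_bound``;
    null: trait 2 has no causal variant.  Returns the two datasets and a
    truth dict with the causal indices.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rho = build_ld_target(n_variants, ("ar1", ld_rho))
    chol = np.linalg.cholesky(condition_psd(rho))
    b = np.sqrt(explained_variance)
    j1 = n_variants // 2
    if scenario == "shared":
        j2 = j1
    elif scenario == "distinct":
        if ld_rho > 0:
            gap = int(np.ceil(np.log(np.sqrt(distinct_r2_bound))
                              / np.log(ld_rho))) + 1
        else:
            gap = 1
        j2 = j1 + gap
        if j2 >= n_variants:
            raise ConfigError(
                "region too small for the requested distinct-variant r² bound"
            )
    elif scenario == "null":
        j2 = None
    else:
        raise ConfigError(f"unknown coloc scenario {scenario!r}")

    mean1 = b * rho[:, j1]
    mean2 = np.zeros(n_variants) if j2 is None else b * rho[:, j2]
    bh1, se1 = sample_marginal_stats(mean1, rho, n1, rng, chol=chol)
    bh2, se2 = sample_marginal_stats(mean2, rho, n2, rng, chol=chol)
    variants = [Variant("17", 47_000_000 + 5_000 * j, f"17:{47_000_000 + 5_000 * j}",
                        "A", "G") for j in range(n_variants)]
    ds1 = dataset_from_arrays(variants, bh1, se1, n1, "trait1", "quantitative")
    ds2 = dataset_from_arrays(variants, bh2, se2, n2, "trait2", "quantitative")
    truth = {"scenario": scenario, "causal1": j1, "causal2": j2,
             "r2_between": None if j2 is None or j2 == j1
             else float(rho[j1, j2] ** 2)}
    return ds1, ds2, truth
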