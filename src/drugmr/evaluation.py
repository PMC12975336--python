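"""Calibration and parameter-recovery studies for the package's estimators.

These routines define the package's reference simulation studies: type-I
error of correlated IVW under the causal null, Cochran's Q calibration under
exact homogeneity, HEIDI rejection under a single shared causal variant,
recovery of a known causal effect with CI coverage, recovery of a planted
mediation proportion, and colocalization behaviour under shared / distinct /
null scenarios.  Replicate counts and cohort sizes are chosen so a full run
completes in minutes on one CPU; each function takes a seed and is fully
reproducible.

Large replicate studies draw marginal summary statistics directly from
their asymptotic sampling distribution (see
:func:`drugmr.simulate.sample_marginal_stats`); the mediation study runs the
full individual-level generator.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from .estimators import cochran_q, ivw_correlated
from .ld import condition_psd
from .pipeline import inputs_from_study, mediation_analysis, run_drug_target_screen
from .coloc import coloc_abf
from .simulate import (
    MediatorSpec,
    SimConfig,
    build_ld_target,
    instrument_set_from_arrays,
    sample_marginal_stats,
    simulate_coloc_scenario,
    simulate_two_sample_study,
)
from .smr import heidi_test

__all__ = [
    "ivw_type1_error",
    "q_calibration",
    "heidi_null_rejection",
    "theta_recovery",
    "mediation_recovery",
    "coloc_scenario_rates",
    "screen_determinism",
]

# reference instrument design: 10 correlated instruments, moderate strength
_M = 10
_GAMMA = 0.1
_LD_RHO = 0.5
_N = 50_000


def _design():
    rho = build_ld_target(_M, ("ar1", _LD_RHO))
    chol = np.linalg.cholesky(condition_psd(rho))
    beta_marginal = rho @ np.full(_M, _GAMMA)
    return rho, chol, beta_marginal


def ivw_type1_error(n_reps: int = 10_000, seed: int = 0,
                    alpha: float = 0.05) -> float:
    """Rejection rate of fixed-effect correlated IVW when the true causal
    effect is zero (outcome associations pure noise)."""
    rng = np.random.default_rng(seed)
    rho, chol, bm = _design()
    sx = np.full(_M, 1.0 / np.sqrt(_N))
    null = np.zeros(_M)
    rej = 0
    for _ in range(n_reps):
        bx, _ = sample_marginal_stats(bm, rho, _N, rng, chol=chol)
        by, sy = sample_marginal_stats(null, rho, _N, rng, chol=chol)
        est = ivw_correlated(
            instrument_set_from_arrays(bx, sx, by, sy, rho), model="fixed")
        rej += est.pvalue < alpha
    return rej / n_reps


def q_calibration(n_reps: int = 10_000, seed: int = 1,
                  alpha: float = 0.05, theta: float = 0.35) -> float:
    """Rejection rate of the generalized Cochran Q under exact homogeneity.

    The homogeneity null holds when every instrument's outcome effect is
    exactly theta times its (observed) exposure effect plus sampling noise —
    the no-measurement-error convention the Q weights assume.
    """
    rng = np.random.default_rng(seed)
    rho, chol, bm = _design()
    sx = np.full(_M, 1.0 / np.sqrt(_N))
    rej = 0
    for _ in range(n_reps):
        bx, _ = sample_marginal_stats(bm, rho, _N, rng, chol=chol)
        by = theta * bx + (chol @ rng.standard_normal(_M)) / np.sqrt(_N)
        sy = np.full(_M, 1.0 / np.sqrt(_N))
        iset = instrument_set_from_arrays(bx, sx, by, sy, rho)
        est = ivw_correlated(iset, model="fixed")
        _, qp = cochran_q(iset, est.theta)
        rej += qp < alpha
    return rej / n_reps


def heidi_null_rejection(n_reps: int = 2_000, seed: int = 2,
                         alpha: float = 0.05) -> float:
    """HEIDI rejection rate when one causal variant truly drives both traits.

    A 30-variant AR(1) region with a strong central QTL (5% of exposure
    variance at n = 20,000) and a proportional outcome signal at
    n = 50,000; well-calibrated HEIDI rejects at close to the nominal rate.
    """
    m, rho_ld, theta = 30, 0.8, 0.3
    rho = build_ld_target(m, ("ar1", rho_ld))
    chol = np.linalg.cholesky(condition_psd(rho))
    gamma = np.zeros(m)
    gamma[m // 2] = np.sqrt(0.05)
    bm = rho @ gamma
    n_x, n_y = 20_000, 50_000
    rng = np.random.default_rng(seed)
    rej = used = 0
    for _ in range(n_reps):
        bx, sx = sample_marginal_stats(bm, rho, n_x, rng, chol=chol)
        by, sy = sample_marginal_stats(theta * bm, rho, n_y, rng, chol=chol)
        iset = instrument_set_from_arrays(bx, sx, by, sy, rho)
        p, k = heidi_test(iset)
        if p is not None:
            used += 1
            rej += p < alpha
    return rej / max(used, 1)


def theta_recovery(n_reps: int = 1_000, seed: int = 3,
                   theta: float = 0.35) -> dict:
    """Bias and 95% CI coverage for the causal effect over replicate studies.

    Each replicate is a two-sample study with 10 correlated instruments and
    n = 50,000 per arm; the estimator is fixed-effect correlated IVW.
    """
    rng = np.random.default_rng(seed)
    rho, chol, bm = _design()
    sx = np.full(_M, 1.0 / np.sqrt(_N))
    thetas = np.empty(n_reps)
    covered = 0
    for i in range(n_reps):
        bx, _ = sample_marginal_stats(bm, rho, _N, rng, chol=chol)
        by, sy = sample_marginal_stats(theta * bm, rho, _N, rng, chol=chol)
        est = ivw_correlated(
            instrument_set_from_arrays(bx, sx, by, sy, rho), model="fixed")
        thetas[i] = est.theta
        covered += est.ci_low <= theta <= est.ci_high
    return {
        "bias": float(thetas.mean() - theta),
        "mc_se": float(thetas.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def _mediation_config(seed: int, n: int = 20_000) -> SimConfig:
    # planted proportion: direct 0.3, alpha 0.5, beta 0.2 -> 0.1/0.4 = 25%
    return SimConfig(
        n_variants=50,
        ld_model=("block", (25, 25), 0.5),
        n_exposure=n, n_outcome=n, n_mediator=n, n_ref=500,
        causal=tuple((j, 0.12) for j in (1, 5, 9, 13, 17, 21)),
        theta_true=0.3,
        mediators=(MediatorSpec("mediator", 0.5, 0.2,
                                causal=((27, 0.15), (34, 0.15), (41, 0.15))),),
        outcome_type="quantitative",
        seed=seed,
    )


def mediation_recovery(n_reps: int = 40, seed: int = 4) -> dict:
    """Recovery of a planted 25% mediation proportion.

    Full individual-level three-sample studies (n = 20,000 per cohort): the
    exposure's causal variants sit in one LD block, the mediator's own
    determinants in a second, uncorrelated block, so the multivariable model
    is identified.  Returns the mean estimated proportion (percent).
    """
    props = []
    for r in range(n_reps):
        study = simulate_two_sample_study(_mediation_config(seed + r))
        med = mediation_analysis(inputs_from_study(study), "mediator")
        props.append(med.proportion_mediated)
    props = np.array(props, dtype=float)
    return {
        "mean_proportion_pct": float(props.mean()),
        "truth_pct": 25.0,
        "mc_se": float(props.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def coloc_scenario_rates(n_reps: int = 200, seed: int = 5) -> dict:
    """Colocalization success rates under shared and distinct scenarios.

    shared: fraction of replicates with PP4 > 0.9; distinct: fraction with
    PP3 > PP4 (r² between the two causal variants < 0.01).  Each replicate
    is a 100-variant AR(1) region, 1% explained variance per trait,
    n = 20,000 per trait.
    """
    rng = np.random.default_rng(seed)
    shared_hit = distinct_hit = 0
    for _ in range(n_reps):
        ds1, ds2, _ = simulate_coloc_scenario("shared", seed=rng)
        shared_hit += coloc_abf(ds1, ds2).pp[4] > 0.9
        ds1, ds2, _ = simulate_coloc_scenario("distinct", seed=rng)
        pp = coloc_abf(ds1, ds2).pp
        distinct_hit += pp[3] > pp[4]
    return {
        "shared_pp4_gt_0.9_rate": shared_hit / n_reps,
        "distinct_pp3_gt_pp4_rate": distinct_hit / n_reps,
        "n_reps": n_reps,
    }


def _screen_config(seed: int) -> dict:
    return {
        "seed": seed,
        "simulate": {
            "n_variants": 50,
            "ld_model": ["ar1", 0.7],
            "n_exposure": 6_000, "n_outcome": 6_000, "n_mediator": 4_000,
            "n_ref": 500,
            "causal": [[j, 0.12] for j in range(2, 50, 5)],
            "theta_true": 0.3,
            "outcome_type": "binary", "binary_engine": "linear",
            "mediators": [
                {"name": "metabolite_a", "alpha_true": 0.5, "beta_true": 0.2,
                 "causal": [[0, 0.15], [24, 0.15]], "family": "metabolite"},
                {"name": "protein_b", "alpha_true": 0.4, "beta_true": 0.3,
                 "causal": [[10, 0.2], [35, 0.2]], "family": "protein"},
            ],
            "ancestries": [{"name": "EAS"}, {"name": "EUR"}],
        },
        "mediation_features": ["metabolite_a"],
        "protein_features": ["protein_b"],
    }


def screen_determinism(workdir, seed: int = 6) -> bool:
    """Run the full screen twice with one seed; True iff outputs are
    byte-identical."""
    workdir = Path(workdir)
    config = _screen_config(seed)
    run_drug_target_screen(config, workdir / "run1")
    run_drug_target_screen(config, workdir / "run2")
    files = sorted(p.name for p in (workdir / "run1").iterdir())
    return all(
        filecmp.cmp(workdir / "run1" / f, workdir / "run2" / f, shallow=False)
        for f in files
    )
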