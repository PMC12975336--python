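"""Config-driven drug-target screen: the package's analysis graph.

For each ancestry the screen selects drug-target-region instruments from the
exposure GWAS, removes outcome-associated instruments, rescales effects to a
one-SD exposure decrease, and estimates causal effects of genetically
proxied target inhibition on every molecular feature and on the disease
outcome (correlated IVW, with MR-Egger and Cochran's Q where enough
instruments exist).  Feature-level estimates are pooled across ancestries by
fixed-effect meta-analysis and FDR-controlled within feature families.
Nominated mediators get product-of-coefficients mediation; nominated
proteins get colocalization and SMR/HEIDI against the outcome.

Failures are contained per feature: a feature whose instruments cannot be
built is recorded with its error and the screen continues (omics-wide
screens routinely contain features without valid instruments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import classify_coloc, coloc_abf
from .errors import DrugMRError
from .estimators import ivw_correlated, mr_egger_correlated, mvmr_correlated
from .ld import (
    GeneRegionSpec,
    InstrumentSet,
    LDMatrix,
    build_instrument_set,
    clump,
    drop_outcome_associated,
    scale_to_sd_decrease,
    select_gene_region_instruments,
)
from .meta import bh_fdr, fixed_effect_meta, mediation_product
from .simulate import MediatorSpec, SimConfig, simulate_two_sample_study
from .smr import heidi_test, smr_multi, smr_test
from .sumstats import SummaryDataset, harmonize, read_sumstats

__all__ = [
    "DEFAULT_THRESHOLDS",
    "StudyInputs",
    "inputs_from_study",
    "mediation_analysis",
    "run_drug_target_screen",
]

#: the screen's default decision thresholds
DEFAULT_THRESHOLDS = {
    "instrument_p": 1e-8,
    "r2": 0.3,
    "window_bp": 1_000_000,
    "outcome_p": 5e-8,
    "p1": 1e-4,
    "p2": 1e-4,
    "p12": 1e-5,
    "pp4": 0.7,
    "heidi_p": 0.05,
    "fdr": 0.05,
    "reverse_r2": 0.05,
    "reverse_p": 5e-8,
}


@dataclass
class StudyInputs:
    """One ancestry's data: exposure, outcome, molecular features, LD."""

    ancestry: str
    exposure: SummaryDataset
    outcome: SummaryDataset
    features: dict = field(default_factory=dict)   # name -> SummaryDataset
    families: dict = field(default_factory=dict)   # name -> family label
    ld: LDMatrix | None = None
    region: GeneRegionSpec | None = None
    exposure_sd: float = 1.0
    truth: object = None


def _inputs_from_simulation(sim_cfg: dict, ancestry: dict, seed: int,
                            thresholds: dict) -> StudyInputs:
    med_specs = tuple(
        MediatorSpec(
            name=m["name"],
            alpha_true=float(m.get("alpha_true", 0.0)),
            beta_true=float(m.get("beta_true", 0.0)),
            causal=tuple(tuple(c) for c in m.get("causal", ())),
        )
        for m in sim_cfg.get("mediators", [])
    )
    config = SimConfig(
        n_variants=int(sim_cfg.get("n_variants", 50)),
        ld_model=tuple(sim_cfg.get("ld_model", ("ar1", 0.7))),
        n_exposure=int(ancestry.get("n_exposure", sim_cfg.get("n_exposure", 20_000))),
        n_outcome=int(ancestry.get("n_outcome", sim_cfg.get("n_outcome", 20_000))),
        n_mediator=int(ancestry.get("n_mediator", sim_cfg.get("n_mediator", 10_000))),
        n_ref=int(sim_cfg.get("n_ref", 500)),
        causal=tuple(tuple(c) for c in sim_cfg.get(
            "causal", [[j, 0.12] for j in range(2, 50, 5)])),
        theta_true=float(sim_cfg.get("theta_true", 0.35)),
        mediators=med_specs,
        outcome_type=sim_cfg.get("outcome_type", "binary"),
        prevalence=float(sim_cfg.get("prevalence", 0.1)),
        binary_engine=sim_cfg.get("binary_engine", "linear"),
        seed=int(ancestry.get("seed", seed)),
    )
    study = simulate_two_sample_study(config)
    families = {m["name"]: m.get("family", "metabolite")
                for m in sim_cfg.get("mediators", [])}
    features = dict(study.mediators)
    families[study.outcome.trait_id] = "outcome"
    features[study.outcome.trait_id] = study.outcome
    region = GeneRegionSpec("HMGCR", config.chrom, config.region_tss,
                            int(thresholds["window_bp"]))
    return StudyInputs(
        ancestry=ancestry["name"],
        exposure=study.exposure,
        outcome=study.outcome,
        features=features,
        families=families,
        ld=study.ld,
        region=region,
        exposure_sd=study.truth.exposure_sd,
        truth=study.truth,
    )


def _inputs_from_paths(paths: dict, thresholds: dict) -> StudyInputs:
    exposure = read_sumstats(paths["exposure"], trait_id="exposure",
                             ancestry=paths.get("name", "other"))
    outcome = read_sumstats(paths["outcome"], trait_id="outcome",
                            trait_type=paths.get("outcome_type", "binary"),
                            ancestry=paths.get("name", "other"))
    ld = LDMatrix.from_files(paths["ld_matrix"], paths["ld_variants"])
    features = {"outcome": outcome}
    families = {"outcome": "outcome"}
    for feat in paths.get("features", []):
        features[feat["name"]] = read_sumstats(
            feat["path"], trait_id=feat["name"],
            ancestry=paths.get("name", "other"))
        families[feat["name"]] = feat.get("family", "metabolite")
    gene = paths.get("gene", "HMGCR")
    if "tss" in paths:
        region = GeneRegionSpec(gene, str(paths["chrom"]), int(paths["tss"]),
                                int(thresholds["window_bp"]))
    else:
        region = GeneRegionSpec.from_gene(gene, int(thresholds["window_bp"]))
    return StudyInputs(
        ancestry=paths.get("name", "other"), exposure=exposure,
        outcome=outcome, features=features, families=families,
        ld=ld, region=region,
        exposure_sd=float(paths.get("exposure_sd", 1.0)),
    )


def _feature_instruments(inputs: StudyInputs, feature: SummaryDataset,
                         thresholds: dict,
                         outcome_filter: bool = True) -> InstrumentSet:
    iset = select_gene_region_instruments(
        inputs.exposure, feature, inputs.region, inputs.ld,
        p_max=float(thresholds["instrument_p"]),
        r2_max=float(thresholds["r2"]),
    )
    # The exclusion-restriction guard applies in the screen, where a
    # direct instrument-outcome association signals pleiotropy.  Mediation
    # re-estimates the total effect, for which instrument-outcome
    # association is exactly what the causal model predicts.
    if outcome_filter and feature.trait_id == inputs.outcome.trait_id:
        iset = drop_outcome_associated(iset, float(thresholds["outcome_p"]))
    return scale_to_sd_decrease(iset, inputs.exposure_sd)


def _mvmr_instruments(inputs: StudyInputs, mediator: SummaryDataset,
                      thresholds: dict) -> InstrumentSet:
    """Union of exposure- and mediator-selected instruments, two exposure
    columns (exposure, mediator), outcome effects on the disease."""
    p_max = float(thresholds["instrument_p"])
    r2 = float(thresholds["r2"])
    region_x = [r for r in inputs.exposure
                if inputs.region.contains(r.variant)
                and r.variant.key in inputs.ld._index]
    region_m = [r for r in mediator
                if inputs.region.contains(r.variant)
                and r.variant.key in inputs.ld._index]
    kept = {v.key: v for v in clump(region_x, inputs.ld, p_max, r2)}
    for v in clump(region_m, inputs.ld, p_max, r2):
        kept.setdefault(v.key, v)
    if not kept:
        raise DrugMRError("no instruments for multivariable mediation model")
    keys = sorted(kept, key=lambda k: (k[0], k[1]))
    bx, sx, by, sy, variants = [], [], [], [], []
    for k in keys:
        rx = inputs.exposure.records.get(k)
        rm = mediator.records.get(k)
        ry = inputs.outcome.records.get(k)
        if rx is None or rm is None or ry is None:
            continue
        variants.append(rx.variant)
        bx.append([rx.beta, rm.beta])
        sx.append([rx.se, rm.se])
        by.append(ry.beta)
        sy.append(ry.se)
    if len(variants) < 2:
        raise DrugMRError("fewer than 2 shared variants for the MVMR model")
    return InstrumentSet(
        variants=variants, beta_x=np.array(bx), se_x=np.array(sx),
        beta_y=np.array(by), se_y=np.array(sy),
        ld=inputs.ld.subset(variants).conditioned(),
        exposure_ids=[inputs.exposure.trait_id, mediator.trait_id],
        outcome_id=inputs.outcome.trait_id,
    )


def inputs_from_study(study, ancestry: str = "sim",
                      window_bp: int = 1_000_000) -> StudyInputs:
    """Wrap a :class:`~drugmr.simulate.SimulatedStudy` as screen inputs."""
    cfg = study.truth.config
    features = dict(study.mediators)
    features[study.outcome.trait_id] = study.outcome
    families = {name: "metabolite" for name in study.mediators}
    families[study.outcome.trait_id] = "outcome"
    return StudyInputs(
        ancestry=ancestry,
        exposure=study.exposure,
        outcome=study.outcome,
        features=features,
        families=families,
        ld=study.ld,
        region=GeneRegionSpec("HMGCR", cfg["chrom"], cfg["region_tss"],
                              window_bp),
        exposure_sd=study.truth.exposure_sd,
        truth=study.truth,
    )


def mediation_analysis(inputs: StudyInputs, mediator_name: str,
                       thresholds: dict | None = None):
    """Product-of-coefficients mediation for one molecular mediator.

    alpha: exposure→mediator from correlated IVW over drug-target-region
    instruments; beta: mediator→outcome adjusted for the exposure, from
    multivariable MR over the union of exposure- and mediator-selected
    instruments; total: univariable exposure→outcome IVW (the proportion's
    denominator).
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    mediator = inputs.features[mediator_name]
    alpha_est = ivw_correlated(
        _feature_instruments(inputs, mediator, thresholds))
    total_est = ivw_correlated(
        _feature_instruments(inputs, inputs.outcome, thresholds,
                             outcome_filter=False))
    mv = mvmr_correlated(_mvmr_instruments(inputs, mediator, thresholds))
    beta_est = next(e for e in mv if e.exposure_id == mediator_name)
    return mediation_product(
        alpha_est.theta, alpha_est.se,
        beta_est.theta, beta_est.se,
        total_est.theta, total_est.se,
    )


def _region_subset(ds: SummaryDataset, region: GeneRegionSpec) -> SummaryDataset:
    recs = {k: r for k, r in ds.records.items() if region.contains(r.variant)}
    return SummaryDataset(trait_id=ds.trait_id, trait_type=ds.trait_type,
                          ancestry=ds.ancestry, records=recs)


def run_drug_target_screen(config: dict, outdir) -> dict:
    """Run the full screen described by ``config`` and write tidy outputs.

    Returns {"mr": DataFrame, "meta": DataFrame, "mediation": DataFrame,
    "coloc_smr": DataFrame, "errors": DataFrame, "manifest": dict}; TSVs and
    a JSON manifest are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = int(config.get("seed", 0))

    studies: list[StudyInputs] = []
    if "simulate" in config:
        sim_cfg = config["simulate"]
        for i, anc in enumerate(sim_cfg.get(
                "ancestries", [{"name": "EAS"}, {"name": "EUR"}])):
            anc = dict(anc)
            anc.setdefault("seed", seed + 1000 * i)
            studies.append(_inputs_from_simulation(sim_cfg, anc, seed, thresholds))
    for paths in config.get("inputs", []):
        studies.append(_inputs_from_paths(paths, thresholds))
    if not studies:
        raise DrugMRError("config defines neither 'simulate' nor 'inputs'")

    mr_rows, err_rows = [], []
    per_feature: dict[str, list] = {}
    for st in studies:
        for name in sorted(st.features):
            feature = st.features[name]
            try:
                iset = _feature_instruments(st, feature, thresholds)
                est = ivw_correlated(iset)
                row = {
                    "ancestry": st.ancestry, "feature": name,
                    "family": st.families.get(name, "other"),
                    **est.to_dict(),
                }
                if iset.n_snps >= 3:
                    egger = mr_egger_correlated(iset)
                    row["egger_theta"] = egger.theta
                    row["egger_se"] = egger.se
                    row["egger_intercept"] = egger.egger_intercept
                    row["egger_intercept_p"] = egger.egger_intercept_pvalue
                mr_rows.append(row)
                per_feature.setdefault(name, []).append(
                    (st.ancestry, est, st.families.get(name, "other")))
            except (DrugMRError, ZeroDivisionError) as exc:
                err_rows.append({"ancestry": st.ancestry, "feature": name,
                                 "stage": "mr", "error": str(exc)})

    meta_rows = []
    for name in sorted(per_feature):
        entries = per_feature[name]
        res = fixed_effect_meta([(e.theta, e.se) for _, e, _ in entries])
        meta_rows.append({
            "feature": name, "family": entries[0][2],
            "n_ancestries": len(entries),
            "theta_meta": res.theta, "se_meta": res.se,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "pvalue": res.pvalue, "q_meta": res.q_meta,
            "i_squared": res.i_squared,
        })
    meta_df = pd.DataFrame(meta_rows)
    if not meta_df.empty:
        meta_df["fdr_q"] = bh_fdr(meta_df["pvalue"].to_numpy(),
                                  meta_df["family"].to_numpy())
        meta_df["fdr_significant"] = meta_df["fdr_q"] < float(thresholds["fdr"])

    mediation_rows = []
    for name in config.get("mediation_features", []):
        for st in studies:
            if name not in st.features:
                continue
            try:
                med = mediation_analysis(st, name, thresholds)
                mediation_rows.append({
                    "ancestry": st.ancestry, "mediator": name,
                    "alpha": med.alpha, "se_alpha": med.se_alpha,
                    "beta": med.beta, "se_beta": med.se_beta,
                    "indirect": med.indirect, "se_indirect": med.se_indirect,
                    "total": med.total, "se_total": med.se_total,
                    "proportion_mediated_pct": med.proportion_mediated,
                    "se_fallback_used": med.se_fallback_used,
                })
            except (DrugMRError, StopIteration, ZeroDivisionError) as exc:
                err_rows.append({"ancestry": st.ancestry, "feature": name,
                                 "stage": "mediation", "error": str(exc)})

    coloc_rows = []
    for name in config.get("protein_features", []):
        for st in studies:
            if name not in st.features:
                continue
            try:
                prot = _region_subset(st.features[name], st.region)
                outc = _region_subset(st.outcome, st.region)
                cres = coloc_abf(prot, outc,
                                 p1=float(thresholds["p1"]),
                                 p2=float(thresholds["p2"]),
                                 p12=float(thresholds["p12"]))
                paired = harmonize(prot, outc)
                iset = build_instrument_set(
                    paired, st.ld, exposure_id=name,
                    outcome_id=st.outcome.trait_id)
                zx = iset.beta_x[:, 0] / iset.se_x[:, 0]
                top = int(np.argmax(np.abs(zx)))
                b_smr, p_smr = smr_test(
                    zx[top], iset.beta_y[top] / iset.se_y[top],
                    iset.beta_x[top, 0], iset.beta_y[top])
                p_multi = smr_multi(iset, p_qtl_threshold=5e-8)
                p_heidi, n_heidi = heidi_test(iset)
                heidi_pass = p_heidi is None or p_heidi > float(thresholds["heidi_p"])
                coloc_rows.append({
                    "ancestry": st.ancestry, "protein": name,
                    "n_snps": cres.n_snps,
                    **{f"pp{h}": float(cres.pp[h]) for h in range(5)},
                    "coloc_class": classify_coloc(
                        cres, float(thresholds["pp4"])),
                    "b_smr": b_smr, "or_smr": float(np.exp(b_smr)),
                    "p_smr": p_smr, "p_smr_multi": p_multi,
                    "p_heidi": p_heidi, "n_heidi_snps": n_heidi,
                    "prioritized": bool(
                        cres.pp4 > float(thresholds["pp4"])
                        and heidi_pass and p_smr < 0.05),
                })
            except (DrugMRError, ValueError) as exc:
                err_rows.append({"ancestry": st.ancestry, "feature": name,
                                 "stage": "coloc_smr", "error": str(exc)})

    tables = {
        "mr": pd.DataFrame(mr_rows),
        "meta": meta_df,
        "mediation": pd.DataFrame(mediation_rows),
        "coloc_smr": pd.DataFrame(coloc_rows),
        "errors": pd.DataFrame(err_rows),
    }
    for key, df in tables.items():
        df.to_csv(outdir / f"{key}_results.tsv", sep="\t", index=False,
                  float_format="%.10g")
    manifest = {
        "package": "drugmr",
        "version": __version__,
        "seed": seed,
        "thresholds": thresholds,
        "ancestries": [st.ancestry for st in studies],
        "n_features": {st.ancestry: len(st.features) for st in studies},
        "n_mr_rows": len(mr_rows),
        "n_errors": len(err_rows),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    tables["manifest"] = manifest
    return tables
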