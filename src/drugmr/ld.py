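"""LD estimation, greedy clumping and drug-target-region instrument selection.

The reference panel enters either as a dosage table (variants x samples) or a
VCF; LD is the Pearson correlation of mean-centred dosages.  Subsets of a
sample correlation matrix from a small panel (a few hundred individuals, as
in 1000 Genomes ancestry panels) are frequently indefinite, so every matrix
is conditioned to positive semi-definiteness by an eigenvalue floor before a
GLS solve touches it.

Instrument selection mirrors drug-target MR practice: restrict to a window
around the target gene's transcription start site, keep genome-wide-strong
exposure associations, and greedily clump at an r-squared ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneratePanelError, NoInstrumentsError
from .sumstats import AssociationRecord, SummaryDataset, Variant, harmonize

__all__ = [
    "LDMatrix",
    "GeneRegionSpec",
    "InstrumentSet",
    "GENE_TSS_TABLE",
    "ld_from_genotypes",
    "read_dosage_table",
    "read_dosages_vcf",
    "clump",
    "select_gene_region_instruments",
    "build_instrument_set",
    "scale_to_sd_decrease",
    "drop_outcome_associated",
]

#: Approximate GRCh38 transcription start sites for the drug-target genes the
#: package ships with; override per-analysis via GeneRegionSpec or config.
GENE_TSS_TABLE = {
    "HMGCR": ("5", 75336161),
    "LDLR": ("19", 11089362),
    "PCSK9": ("1", 55039447),
    "GIP": ("17", 47035731),
}

PSD_EIGENVALUE_FLOOR = 1e-10


def condition_psd(r: np.ndarray, floor: float = PSD_EIGENVALUE_FLOOR) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and re-symmetrize; unit diagonal restored."""
    r = np.asarray(r, dtype=float)
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() < floor:
        w = np.clip(w, floor, None)
        r = (v * w) @ v.T
        r = (r + r.T) / 2.0
        # rescale to correlation form; preserves positive semi-definiteness
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class LDMatrix:
    """A correlation matrix over an ordered variant list."""

    variants: list[Variant]
    r: np.ndarray
    n_ref: int = 0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.variants)
        if self.r.shape != (m, m):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({m}, {m})")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if np.abs(self.r).max() > 1.0 + 1e-8:
            raise ValueError("|r| exceeds 1")
        self._index = {v.key: i for i, v in enumerate(self.variants)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def index_of(self, variant: Variant) -> int:
        return self._index[variant.key]

    def subset(self, variants: Sequence[Variant]) -> "LDMatrix":
        idx = [self._index[v.key] for v in variants]
        return LDMatrix(list(variants), self.r[np.ix_(idx, idx)], self.n_ref)

    def conditioned(self, floor: float = PSD_EIGENVALUE_FLOOR) -> "LDMatrix":
        """PSD-conditioned copy (eigenvalue floor + re-symmetrization)."""
        return LDMatrix(self.variants, condition_psd(self.r, floor), self.n_ref)

    def to_files(self, matrix_path, variants_path) -> None:
        np.savetxt(matrix_path, self.r, delimiter="\t", fmt="%.10g")
        pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "rsid": [v.rsid for v in self.variants],
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
            }
        ).to_csv(variants_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, matrix_path, variants_path, n_ref: int = 0) -> "LDMatrix":
        r = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
        vdf = pd.read_csv(variants_path, sep="\t")
        variants = [
            Variant(str(row.chrom), int(row.pos), str(row.rsid),
                    row.effect_allele, row.other_allele)
            for row in vdf.itertuples(index=False)
        ]
        return cls(variants, r, n_ref)


@dataclass(frozen=True)
class GeneRegionSpec:
    """A cis window around a gene's transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    window_bp: int = 1_000_000

    def __post_init__(self):
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")

    @classmethod
    def from_gene(cls, gene_id: str, window_bp: int = 1_000_000) -> "GeneRegionSpec":
        chrom, tss = GENE_TSS_TABLE[gene_id]
        return cls(gene_id, chrom, tss, window_bp)

    def contains(self, variant: Variant) -> bool:
        return variant.chrom == self.chrom and abs(variant.pos - self.tss) <= self.window_bp


@dataclass
class InstrumentSet:
    """Harmonized effect vectors plus their LD submatrix.

    ``beta_x``/``se_x`` are (n_snps, k) with one column per exposure (k = 1
    for univariable MR); ``beta_y``/``se_y`` are length n_snps.
    """

    variants: list[Variant]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    ld: LDMatrix
    exposure_ids: list[str] = field(default_factory=lambda: ["exposure"])
    outcome_id: str = "outcome"

    def __post_init__(self):
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        if self.beta_x.shape[0] == 1 and len(self.variants) != 1:
            self.beta_x = self.beta_x.T
            self.se_x = self.se_x.T
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        m = len(self.variants)
        if not (self.beta_x.shape[0] == self.se_x.shape[0] == m
                and self.beta_y.shape == (m,) and self.se_y.shape == (m,)):
            raise ValueError("instrument vectors have inconsistent lengths")
        if [v.key for v in self.ld.variants] != [v.key for v in self.variants]:
            raise ValueError("LD matrix variant order differs from instrument order")

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]

    def subset(self, indices: Sequence[int]) -> "InstrumentSet":
        idx = list(indices)
        variants = [self.variants[i] for i in idx]
        return InstrumentSet(
            variants=variants,
            beta_x=self.beta_x[idx, :],
            se_x=self.se_x[idx, :],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            ld=self.ld.subset(variants),
            exposure_ids=list(self.exposure_ids),
            outcome_id=self.outcome_id,
        )

    def outcome_pvalues(self) -> np.ndarray:
        """Two-sided normal p-values of the outcome associations."""
        z = np.abs(self.beta_y) / self.se_y
        return 2.0 * stats.norm.sf(z)


# ---------------------------------------------------------------------------
# LD estimation


def ld_from_genotypes(dosages, variants: Sequence[Variant] | None = None,
                      condition: bool = True) -> LDMatrix:
    """Pearson LD from a dosage table (variants x samples).

    ``dosages`` may be a DataFrame (rows = variants, in the order of
    ``variants``) or an ndarray.  Monomorphic variants are dropped.  The
    result is PSD-conditioned unless ``condition`` is False.
    """
    if isinstance(dosages, pd.DataFrame):
        mat = dosages.to_numpy(dtype=float)
    else:
        mat = np.asarray(dosages, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a 2-D dosage table with >= 2 samples")
    m, n = mat.shape
    if variants is None:
        variants = [
            Variant("0", i + 1, f"v{i + 1}", "A", "G") for i in range(m)
        ]
    variants = list(variants)
    if len(variants) != m:
        raise ValueError("variant list length does not match dosage rows")

    sd = mat.std(axis=1)
    poly = sd > 0
    if not poly.any():
        raise DegeneratePanelError("all reference-panel variants are monomorphic")
    mat = mat[poly]
    kept = [v for v, keep in zip(variants, poly) if keep]
    centred = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((centred ** 2).sum(axis=1))
    r = (centred @ centred.T) / np.outer(denom, denom)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    if condition:
        r = condition_psd(r)
    return LDMatrix(kept, r, n_ref=n)


def read_dosage_table(path) -> tuple[pd.DataFrame, list[Variant]]:
    """Read a plain dosage table: columns chrom,pos,rsid,effect_allele,
    other_allele then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "pos", "rsid", "effect_allele", "other_allele"]
    variants = [
        Variant(str(r.chrom), int(r.pos), str(r.rsid), r.effect_allele, r.other_allele)
        for r in df[meta_cols].itertuples(index=False)
    ]
    return df.drop(columns=meta_cols), variants


def read_dosages_vcf(path) -> tuple[pd.DataFrame, list[Variant]]:
    """Extract dosages (DS if present, else GT allele counts) from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, variants = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # multi-allelic sites are out of scope
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            dose = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
        rows.append(dose)
        variants.append(
            Variant(rec.CHROM, rec.POS, rec.ID or f"{rec.CHROM}:{rec.POS}",
                    rec.ALT[0], rec.REF)
        )
    if not rows:
        raise DegeneratePanelError(f"no usable bi-allelic sites in {path}")
    mat = np.vstack(rows)
    # mean-impute sporadic missing dosages
    means = np.nanmean(mat, axis=1, keepdims=True)
    mat = np.where(np.isnan(mat), means, mat)
    return pd.DataFrame(mat), variants


# ---------------------------------------------------------------------------
# clumping and instrument selection


def clump(
    records: Sequence[AssociationRecord],
    ld: LDMatrix,
    p_max: float = 1e-8,
    r2_max: float = 0.3,
) -> list[Variant]:
    """Greedy p-value clumping at an r-squared ceiling.

    Candidates with p < ``p_max`` are visited in ascending-p order (ties
    broken by chrom:pos); each kept variant discards all remaining candidates
    with r² >= ``r2_max`` against it.  Order of the input is irrelevant.
    """
    candidates = [rec for rec in records if rec.pvalue < p_max]
    candidates.sort(key=lambda rec: (rec.pvalue, rec.variant.chrom, rec.variant.pos))
    kept: list[Variant] = []
    kept_idx: list[int] = []
    for rec in candidates:
        i = ld.index_of(rec.variant)
        if all(ld.r[i, j] ** 2 < r2_max for j in kept_idx):
            kept.append(rec.variant)
            kept_idx.append(i)
    return kept


def build_instrument_set(
    harmonized: pd.DataFrame,
    ld: LDMatrix,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> InstrumentSet:
    """Assemble an :class:`InstrumentSet` from a harmonized pair table."""
    variants = [
        Variant(str(r.chrom), int(r.pos), str(r.rsid), r.effect_allele,
                r.other_allele,
                None if pd.isna(r.eaf_x) else float(r.eaf_x))
        for r in harmonized.itertuples(index=False)
    ]
    return InstrumentSet(
        variants=variants,
        beta_x=harmonized["beta_x"].to_numpy()[:, None],
        se_x=harmonized["se_x"].to_numpy()[:, None],
        beta_y=harmonized["beta_y"].to_numpy(),
        se_y=harmonized["se_y"].to_numpy(),
        ld=ld.subset(variants).conditioned(),
        exposure_ids=[exposure_id],
        outcome_id=outcome_id,
    )


def select_gene_region_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    region: GeneRegionSpec,
    ld: LDMatrix,
    p_max: float = 1e-8,
    r2_max: float = 0.3,
    palindrome_policy: str = "freq_infer",
) -> InstrumentSet:
    """Drug-target instrument selection: cis window, p threshold, clumping.

    Restricts the exposure to ``tss ± window_bp``, clumps at (``p_max``,
    ``r2_max``), harmonizes against the outcome and returns the instrument
    set with its LD submatrix.
    """
    region_recs = [
        rec for rec in exposure
        if region.contains(rec.variant) and rec.variant.key in ld._index
    ]
    if not region_recs:
        raise NoInstrumentsError(
            f"no exposure variant in LD panel within {region.gene_id} "
            f"({region.chrom}:{region.tss}±{region.window_bp})"
        )
    kept = clump(region_recs, ld, p_max=p_max, r2_max=r2_max)
    if not kept:
        raise NoInstrumentsError(
            f"no variant in {region.gene_id} region passes p < {p_max}"
        )
    kept_keys = {v.key for v in kept}
    exp_sub = SummaryDataset(
        trait_id=exposure.trait_id, trait_type=exposure.trait_type,
        ancestry=exposure.ancestry,
        records={k: r for k, r in exposure.records.items() if k in kept_keys},
    )
    paired = harmonize(exp_sub, outcome, palindrome_policy=palindrome_policy)
    if paired.empty:
        raise NoInstrumentsError(
            f"no clumped {region.gene_id} instrument survives harmonization"
        )
    return build_instrument_set(
        paired, ld, exposure_id=exposure.trait_id, outcome_id=outcome.trait_id
    )


def scale_to_sd_decrease(instruments: InstrumentSet, exposure_sd: float) -> InstrumentSet:
    """Rescale exposure effects to a one-SD *decrease* of the exposure.

    Exposure betas (and SEs) are divided by ``exposure_sd`` and the betas
    negated, so downstream causal estimates are per 1-SD decrease — the
    scaling used when a lipid-lowering drug effect is proxied genetically.
    Outcome effects are untouched.  Applying twice with sd = 1 is the
    identity.
    """
    if not exposure_sd > 0:
        raise ValueError(f"exposure_sd must be positive, got {exposure_sd}")
    return replace(
        instruments,
        beta_x=-instruments.beta_x / exposure_sd,
        se_x=instruments.se_x / exposure_sd,
        variants=list(instruments.variants),
    )


def drop_outcome_associated(
    instruments: InstrumentSet, outcome_p_threshold: float = 5e-8
) -> InstrumentSet:
    """Remove instruments directly associated with the outcome.

    Guards the exclusion-restriction assumption: a variant with a
    genome-wide-significant outcome association (normal-approximation p below
    the threshold) is excluded from the instrument set.
    """
    if instruments.n_snps == 0:
        raise NoInstrumentsError("instrument set is empty")
    p_out = instruments.outcome_pvalues()
    keep = np.flatnonzero(p_out >= outcome_p_threshold)
    if keep.size == 0:
        raise NoInstrumentsError(
            f"every instrument has outcome p < {outcome_p_threshold}"
        )
    if keep.size == instruments.n_snps:
        return instruments
    return instruments.subset(keep)
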