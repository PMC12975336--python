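"""GWAS summary statistics: data model, I/O and cross-dataset harmonization.

The central objects are :class:`Variant`, :class:`AssociationRecord` and
:class:`SummaryDataset`.  Files are read and written in the COJO ``.ma``
dialect (``SNP A1 A2 freq b se p N``, A1 = effect allele) or a generic TSV
with a caller-supplied column map.  :func:`harmonize` aligns an outcome
dataset to an exposure dataset's effect alleles, the prerequisite for every
two-sample analysis downstream.

Variant identity throughout is ``chrom:pos`` plus the unordered allele pair;
rsid is carried along but never used for matching.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDatasetError, EmptyIntersectionError, FormatError

__all__ = [
    "Variant",
    "AssociationRecord",
    "SummaryDataset",
    "LoadReport",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
]

_VALID_BASES = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: columns of the COJO .ma dialect, in order
COJO_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def _is_allele(a: str) -> bool:
    return len(a) >= 1 and set(a) <= _VALID_BASES


@dataclass(frozen=True)
class Variant:
    """A bi-allelic variant with an orientation (effect vs other allele)."""

    chrom: str
    pos: int
    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None = None

    def __post_init__(self):
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        object.__setattr__(self, "chrom", str(self.chrom))
        if not (_is_allele(ea) and _is_allele(oa)):
            raise ValueError(f"invalid alleles {ea!r}/{oa!r}")
        if ea == oa:
            raise ValueError(f"effect and other allele identical: {ea}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"eaf {self.eaf} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, tuple[str, str]]:
        """Positional identity: chrom, pos, alleles sorted lexicographically."""
        return (self.chrom, self.pos, tuple(sorted((self.effect_allele, self.other_allele))))

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G pairs — indistinguishable from their strand complement."""
        return self.other_allele == self.effect_allele.translate(_COMPLEMENT)

    def flipped(self) -> "Variant":
        """Swap effect and other allele, complementing eaf."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's marginal association with one trait."""

    variant: Variant
    beta: float
    se: float
    pvalue: float
    n: float
    trait_id: str = ""
    ancestry: str = "other"

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"se must be positive, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue {self.pvalue} outside (0, 1]")
        # Sanity: the reported p should roughly agree with |beta/se| under the
        # normal approximation.  More than two orders of magnitude off is
        # suspicious but not fatal (rounded or exact-test p-values occur in
        # real files), so warn only.
        z = abs(self.beta) / self.se
        p_norm = 2.0 * stats.norm.sf(z)
        if p_norm > 0 and self.pvalue > 0:
            ratio = math.log10(self.pvalue) - math.log10(max(p_norm, 1e-320))
            if abs(ratio) > 2.0:
                warnings.warn(
                    f"{self.variant.rsid}: reported p={self.pvalue:.3g} is "
                    f">2 orders of magnitude from normal-approx "
                    f"p={p_norm:.3g}",
                    stacklevel=2,
                )


@dataclass
class LoadReport:
    """Row bookkeeping for a file load; rows_in = rows_kept + rows_rejected."""

    rows_in: int = 0
    rows_kept: int = 0
    rows_rejected: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str, count: int = 1) -> None:
        self.rows_rejected += count
        self.reasons[reason] = self.reasons.get(reason, 0) + count


@dataclass
class SummaryDataset:
    """A trait's summary statistics keyed by positional variant identity."""

    trait_id: str
    trait_type: Literal["quantitative", "binary"] = "quantitative"
    ancestry: str = "other"
    records: dict = field(default_factory=dict)
    load_report: LoadReport | None = None

    def add(self, record: AssociationRecord) -> None:
        key = record.variant.key
        if key in self.records:
            raise ValueError(f"duplicate variant key {key}")
        self.records[key] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def get(self, key):
        return self.records.get(key)

    @classmethod
    def from_records(
        cls,
        records: Iterable[AssociationRecord],
        trait_id: str,
        trait_type: str = "quantitative",
        ancestry: str = "other",
    ) -> "SummaryDataset":
        ds = cls(trait_id=trait_id, trait_type=trait_type, ancestry=ancestry)
        for rec in records:
            ds.add(rec)
        return ds

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "rsid": r.variant.rsid,
                "effect_allele": r.variant.effect_allele,
                "other_allele": r.variant.other_allele,
                "eaf": r.variant.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows)


def _parse_rsid_position(rsid: str) -> tuple[str, int]:
    """Recover chrom/pos from ``chrom:pos[:...]``-style identifiers.

    The .ma dialect has no position columns; simulated and many real files
    encode them in the SNP id.  Pure rs-numbers yield chrom="0", pos=row order.
    """
    parts = rsid.split(":")
    if len(parts) >= 2:
        try:
            return parts[0], int(parts[1])
        except ValueError:
            pass
    return "0", -1


def read_sumstats(
    path,
    dialect: Literal["cojo_ma", "generic_tsv"] = "cojo_ma",
    column_map: dict[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    ancestry: str = "other",
) -> SummaryDataset:
    """Read a summary-statistics file into a :class:`SummaryDataset`.

    Rows with non-positive SE or unparseable alleles are dropped and counted
    in ``dataset.load_report``.  A missing p column is recomputed from
    ``|beta/se|`` via the normal approximation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "cojo_ma":
        df = pd.read_csv(path, sep=r"\s+")
        required = COJO_COLUMNS[:6]  # p and N tolerated missing
        colmap = {
            "SNP": "rsid", "A1": "effect_allele", "A2": "other_allele",
            "freq": "eaf", "b": "beta", "se": "se", "p": "pvalue", "N": "n",
        }
    elif dialect == "generic_tsv":
        if column_map is None:
            raise FormatError("generic_tsv requires a column_map")
        df = pd.read_csv(path, sep="\t")
        required = [c for c in column_map if column_map[c] in
                    ("rsid", "effect_allele", "other_allele", "beta", "se")]
        colmap = dict(column_map)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    for col in required:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    if df.empty:
        raise EmptyDatasetError(f"{path} contains a header but no data rows")

    df = df.rename(columns=colmap)
    report = LoadReport(rows_in=len(df))
    ds = SummaryDataset(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        ancestry=ancestry,
        load_report=report,
    )
    has_pos = {"chrom", "pos"} <= set(df.columns)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ea = str(row.effect_allele).upper()
            oa = str(row.other_allele).upper()
            if not (_is_allele(ea) and _is_allele(oa)) or ea == oa:
                report.reject("bad_alleles")
                continue
            se = float(row.se)
            if not se > 0 or not math.isfinite(se):
                report.reject("nonpositive_se")
                continue
            beta = float(row.beta)
            if not math.isfinite(beta):
                report.reject("nonfinite_beta")
                continue
            rsid = str(row.rsid)
            if has_pos:
                chrom, pos = str(row.chrom), int(row.pos)
            else:
                chrom, pos = _parse_rsid_position(rsid)
                if pos < 0:
                    pos = i + 1  # stable fallback ordering
            eaf = getattr(row, "eaf", None)
            eaf = None if eaf is None or pd.isna(eaf) else float(eaf)
            pval = getattr(row, "pvalue", None)
            if pval is None or pd.isna(pval):
                pval = max(2.0 * stats.norm.sf(abs(beta) / se), 1e-320)
            pval = min(max(float(pval), 1e-320), 1.0)
            n = getattr(row, "n", None)
            n = float("nan") if n is None or pd.isna(n) else float(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = AssociationRecord(
                    variant=Variant(chrom, pos, rsid, ea, oa, eaf),
                    beta=beta, se=se, pvalue=pval, n=n,
                    trait_id=ds.trait_id, ancestry=ancestry,
                )
            ds.add(rec)
            report.rows_kept += 1
        except (ValueError, TypeError):
            report.reject("unparseable_row")
    if len(ds) == 0:
        raise EmptyDatasetError(f"no usable rows in {path}")
    return ds


def write_sumstats(dataset: SummaryDataset, path, dialect: str = "cojo_ma") -> None:
    """Write a dataset with deterministic column order and >=6 significant digits."""
    if len(dataset) == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    if dialect != "cojo_ma":
        raise FormatError(f"write supports the cojo_ma dialect only, got {dialect!r}")
    rows = []
    for rec in dataset:
        v = rec.variant
        rsid = v.rsid if v.rsid else f"{v.chrom}:{v.pos}"
        rows.append({
            "SNP": rsid, "A1": v.effect_allele, "A2": v.other_allele,
            "freq": float("nan") if v.eaf is None else v.eaf,
            "b": rec.beta, "se": rec.se, "p": rec.pvalue, "N": rec.n,
        })
    pd.DataFrame(rows, columns=COJO_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.8g", na_rep="NA"
    )


# ---------------------------------------------------------------------------
# harmonization


def _match_orientation(vx: Variant, vy: Variant) -> str | None:
    """How does the outcome variant's coding relate to the exposure's?

    Returns "same", "swap", or None when the allele pairs are irreconcilable
    even after strand complementation.  Palindromic pairs are resolved later
    by frequency, not here.
    """
    ex, ox = vx.effect_allele, vx.other_allele
    ey, oy = vy.effect_allele, vy.other_allele
    if (ey, oy) == (ex, ox):
        return "same"
    if (ey, oy) == (ox, ex):
        return "swap"
    cey, coy = ey.translate(_COMPLEMENT), oy.translate(_COMPLEMENT)
    if (cey, coy) == (ex, ox):
        return "same"
    if (cey, coy) == (ox, ex):
        return "swap"
    return None


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_policy: str = "freq_infer",
    maf_ambiguity_bound: float = 0.42,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect alleles.

    Variants are matched on chrom:pos.  When the outcome's effect allele is
    the exposure's other allele, the outcome beta sign is flipped and its eaf
    complemented.  Palindromic (A/T, C/G) variants are resolved by allele
    frequency under ``freq_infer`` — dropped when either eaf is missing or
    when either minor-allele frequency exceeds ``maf_ambiguity_bound`` — or
    dropped outright under ``drop``.  Multi-allelic positions and
    irreconcilable allele pairs are dropped and logged.

    Returns a DataFrame with one row per harmonized variant and a
    ``LoadReport`` in ``df.attrs["report"]``.
    """
    if palindrome_policy not in ("drop", "freq_infer"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    by_pos_x: dict[tuple[str, int], list[AssociationRecord]] = {}
    for rec in exposure:
        by_pos_x.setdefault((rec.variant.chrom, rec.variant.pos), []).append(rec)
    by_pos_y: dict[tuple[str, int], list[AssociationRecord]] = {}
    for rec in outcome:
        by_pos_y.setdefault((rec.variant.chrom, rec.variant.pos), []).append(rec)

    shared = sorted(set(by_pos_x) & set(by_pos_y), key=lambda k: (k[0], k[1]))
    if not shared:
        raise EmptyIntersectionError(
            f"{exposure.trait_id} and {outcome.trait_id} share no positions"
        )

    report = LoadReport(rows_in=len(shared))
    rows = []
    for pos_key in shared:
        recs_x, recs_y = by_pos_x[pos_key], by_pos_y[pos_key]
        if len(recs_x) > 1 or len(recs_y) > 1:
            report.reject("multiallelic")
            continue
        rx, ry = recs_x[0], recs_y[0]
        vx, vy = rx.variant, ry.variant

        if vx.is_palindromic:
            # allele letters cannot distinguish strands; use frequencies
            if not vy.is_palindromic:
                report.reject("allele_mismatch")
                continue
            if {vy.effect_allele, vy.other_allele} != {vx.effect_allele, vx.other_allele}:
                report.reject("allele_mismatch")
                continue
            if palindrome_policy == "drop":
                report.reject("palindromic")
                continue
            if vx.eaf is None or vy.eaf is None:
                report.reject("palindromic_no_freq")
                continue
            maf_x = min(vx.eaf, 1.0 - vx.eaf)
            maf_y = min(vy.eaf, 1.0 - vy.eaf)
            if maf_x > maf_ambiguity_bound or maf_y > maf_ambiguity_bound:
                report.reject("palindromic_ambiguous")
                continue
            flip = (vx.eaf - 0.5) * (vy.eaf - 0.5) < 0
        else:
            orient = _match_orientation(vx, vy)
            if orient is None:
                report.reject("allele_mismatch")
                continue
            flip = orient == "swap"

        beta_y = -ry.beta if flip else ry.beta
        eaf_y = ry.variant.eaf
        if flip and eaf_y is not None:
            eaf_y = 1.0 - eaf_y
        rows.append({
            "chrom": vx.chrom, "pos": vx.pos, "rsid": vx.rsid,
            "effect_allele": vx.effect_allele, "other_allele": vx.other_allele,
            "eaf_x": vx.eaf, "eaf_y": eaf_y,
            "beta_x": rx.beta, "se_x": rx.se, "p_x": rx.pvalue, "n_x": rx.n,
            "beta_y": beta_y, "se_y": ry.se, "p_y": ry.pvalue, "n_y": ry.n,
            "flipped": bool(flip),
        })
        report.rows_kept += 1

    df = pd.DataFrame(rows)
    df.attrs["report"] = report
    df.attrs["exposure_id"] = exposure.trait_id
    df.attrs["outcome_id"] = outcome.trait_id
    return df
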