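"""Genotype I/O, risk-allele dosage coding and Hardy-Weinberg QC.

Genotypes are held as risk-allele counts in {0, 1, 2} per subject x SNP,
with a boolean missing mask. Two on-disk dialects are supported: a plain
tabular TSV (subjects in rows, rsIDs in columns, cells 0/1/2 or NA) and
VCF v4.x with GT fields, where the panel's risk allele is matched against
REF/ALT so dosage is inverted automatically when the risk allele is REF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .snp_panel import SNPPanel

__all__ = [
    "GenotypeMatrix",
    "GenotypeError",
    "HWEResult",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "hwe_exact_test",
    "hwe_report",
    "filter_complete",
]

logger = logging.getLogger(__name__)


class GenotypeError(ValueError):
    """Raised for malformed genotype inputs or panel mismatches."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs risk-allele counts with a missing mask.

    ``counts`` entries are meaningful only where ``missing`` is False;
    masked entries are stored as 0. Column order follows the panel.
    """

    subject_ids: list[str]
    rsids: list[str]
    counts: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.counts.shape
        if len(self.subject_ids) != n or len(self.rsids) != m:
            raise GenotypeError("counts shape does not match subject/rsid labels")
        if self.missing.shape != self.counts.shape:
            raise GenotypeError("missing mask shape does not match counts")
        valid = self.counts[~self.missing]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise GenotypeError("risk-allele counts must lie in {0, 1, 2}")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of subjects with no missing genotype."""
        return ~self.missing.any(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts.astype(float), index=self.subject_ids, columns=self.rsids)
        df[self.missing] = np.nan
        df.index.name = "subject_id"
        return df

    def genotype_counts(self, snp_index: int) -> tuple[int, int, int]:
        """(hom-risk, het, hom-nonrisk) counts at one SNP, missing excluded."""
        col = self.counts[:, snp_index][~self.missing[:, snp_index]]
        return int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())


@dataclass(frozen=True)
class HWEResult:
    """Exact Hardy-Weinberg test result for one SNP."""

    rsid: str
    n_hom_risk: int
    n_het: int
    n_hom_nonrisk: int
    p_exact: float


def _read_tabular(path: Path, panel: SNPPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing_rsids = [r for r in panel.rsids if r not in df.columns]
    if missing_rsids:
        raise GenotypeError(f"panel rsIDs absent from {path}: {missing_rsids}")
    df = df[panel.rsids]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    missing = ~np.isfinite(values)
    counts = np.where(missing, 0, values)
    if np.any((counts != np.round(counts)) | (counts < 0) | (counts > 2)):
        raise GenotypeError(f"{path}: tabular genotype cells must be 0, 1, 2 or NA")
    return GenotypeMatrix(
        subject_ids=[str(s) for s in df.index],
        rsids=list(panel.rsids),
        counts=counts.astype(np.int64),
        missing=missing,
    )


def _read_vcf(path: Path, panel: SNPPanel) -> GenotypeMatrix:
    import pysam

    vcf = pysam.VariantFile(str(path))
    subjects = list(vcf.header.samples)
    by_rsid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    wanted = set(panel.rsids)
    for rec in vcf:
        if rec.id not in wanted:
            continue
        if rec.alts is None or len(rec.alts) != 1:
            raise GenotypeError(f"{rec.id}: multi-allelic or ALT-less site; biallelic SNPs required")
        snp = panel.get(rec.id)
        if snp.risk_allele == rec.ref:
            risk_is_alt = False
        elif snp.risk_allele == rec.alts[0]:
            risk_is_alt = True
        else:
            raise GenotypeError(
                f"{rec.id}: risk allele {snp.risk_allele} matches neither "
                f"REF={rec.ref} nor ALT={rec.alts[0]}"
            )
        counts = np.zeros(len(subjects), dtype=np.int64)
        missing = np.zeros(len(subjects), dtype=bool)
        for i, sample in enumerate(subjects):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                missing[i] = True
                continue
            alt_dosage = sum(int(a > 0) for a in gt)
            counts[i] = alt_dosage if risk_is_alt else len(gt) - alt_dosage
        by_rsid[rec.id] = (counts, missing)
    vcf.close()
    absent = [r for r in panel.rsids if r not in by_rsid]
    if absent:
        raise GenotypeError(f"panel rsIDs absent from {path}: {absent}")
    counts = np.column_stack([by_rsid[r][0] for r in panel.rsids])
    missing = np.column_stack([by_rsid[r][1] for r in panel.rsids])
    return GenotypeMatrix(subjects, list(panel.rsids), counts, missing)


def read_genotypes(path: str | Path, panel: SNPPanel) -> GenotypeMatrix:
    """Read genotypes from a VCF (``.vcf``) or tabular TSV, coded as risk-allele counts."""
    path = Path(path)
    if path.suffix.lower() == ".vcf" or path.name.lower().endswith(".vcf.gz"):
        return _read_vcf(path, panel)
    return _read_tabular(path, panel)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular dialect; round-trips exactly through :func:`read_genotypes`."""
    df = gm.to_dataframe()
    out = df.astype("Int64")
    out.to_csv(path, sep="\t", na_rep="NA")


_COMPLEMENTARY = {"A": "G", "C": "T", "G": "A", "T": "C"}


def write_genotypes_vcf(
    gm: GenotypeMatrix,
    panel: SNPPanel,
    path: str | Path,
    risk_as_ref: tuple[str, ...] = (),
) -> None:
    """Write an uncompressed VCF v4.2 with one record per panel SNP.

    Positions are synthetic placeholders (the analysis never uses them).
    By default the risk allele is written as ALT; rsIDs listed in
    ``risk_as_ref`` are written with the risk allele as REF instead, so
    readers must handle both orientations.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add("1", length=250_000_000)
    for s in gm.subject_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, snp in enumerate(panel):
            other = _COMPLEMENTARY[snp.risk_allele]
            if snp.rsid in risk_as_ref:
                ref, alt, risk_is_alt = snp.risk_allele, other, False
            else:
                ref, alt, risk_is_alt = other, snp.risk_allele, True
            rec = out.new_record(
                contig="1", start=1000 * (j + 1), alleles=(ref, alt), id=snp.rsid
            )
            for i, sample in enumerate(gm.subject_ids):
                if gm.missing[i, j]:
                    rec.samples[sample]["GT"] = (None, None)
                    continue
                risk = int(gm.counts[i, j])
                alt_dosage = risk if risk_is_alt else 2 - risk
                rec.samples[sample]["GT"] = tuple(
                    [1] * alt_dosage + [0] * (2 - alt_dosage)
                )
            out.write(rec)


def hwe_exact_test(n_hom_risk: int, n_het: int, n_hom_nonrisk: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration (Wigginton-style probability
    ordering). Monomorphic sites return 1.0.
    """
    for v in (n_hom_risk, n_het, n_hom_nonrisk):
        if int(v) != v or v < 0:
            raise GenotypeError("genotype counts must be non-negative integers")
    n_hom_risk, n_het, n_hom_nonrisk = int(n_hom_risk), int(n_het), int(n_hom_nonrisk)
    n = n_hom_risk + n_het + n_hom_nonrisk
    if n == 0:
        raise GenotypeError("at least one genotype must be observed")
    n_rare = 2 * min(n_hom_risk, n_hom_nonrisk) + n_het
    if n_rare == 0:
        return 1.0
    # all heterozygote counts compatible with the allele totals (same parity)
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
        - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_het)[0]
    p = probs[probs <= probs[obs] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_report(gm: GenotypeMatrix, panel: SNPPanel) -> pd.DataFrame:
    """Per-SNP exact HWE p-values as a QC table (no auto-exclusion)."""
    rows = []
    for j, snp in enumerate(panel):
        hom_r, het, hom_n = gm.genotype_counts(j)
        rows.append(
            HWEResult(snp.rsid, hom_r, het, hom_n, hwe_exact_test(hom_r, het, hom_n))
        )
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in rows],
            "n_hom_risk": [r.n_hom_risk for r in rows],
            "n_het": [r.n_het for r in rows],
            "n_hom_nonrisk": [r.n_hom_nonrisk for r in rows],
            "p_hwe_exact": [r.p_exact for r in rows],
        }
    )


def filter_complete(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    required_columns: list[str] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Complete-case filter over aligned genotype and phenotype tables.

    Keeps subjects present in both inputs with a complete genotype row and
    non-missing values in ``required_columns`` (default: all phenotype
    columns). Returns filtered copies plus a bookkeeping dict; an empty
    intersection is an error.
    """
    if "subject_id" in phenotypes.columns:
        phen = phenotypes.set_index("subject_id")
    else:
        phen = phenotypes.copy()
    cols = list(required_columns) if required_columns is not None else list(phen.columns)
    sids = pd.Index(gm.subject_ids)
    in_phen = sids.isin(phen.index)
    geno_ok = gm.complete_rows()
    phen_ok = np.zeros(gm.n_subjects, dtype=bool)
    present = sids[in_phen]
    phen_ok[in_phen] = ~phen.loc[present, cols].isna().any(axis=1).to_numpy()
    keep = in_phen & geno_ok & phen_ok
    n_geno_dropped = int((in_phen & ~geno_ok).sum())
    n_phen_dropped = int((~in_phen).sum() + (in_phen & geno_ok & ~phen_ok).sum())
    if not keep.any():
        raise GenotypeError("complete-case filter removed every subject")
    keep_ids = list(sids[keep])
    idx = np.flatnonzero(keep)
    filtered = GenotypeMatrix(
        subject_ids=keep_ids,
        rsids=list(gm.rsids),
        counts=gm.counts[idx],
        missing=gm.missing[idx],
    )
    info = {
        "n_input": gm.n_subjects,
        "n_retained": len(keep_ids),
        "n_dropped_genotype": n_geno_dropped,
        "n_dropped_phenotype": n_phen_dropped,
    }
    logger.info(
        "complete-case filter: %(n_input)d -> %(n_retained)d subjects "
        "(%(n_dropped_genotype)d missing genotypes, %(n_dropped_phenotype)d missing phenotypes)",
        info,
    )
    return filtered, phen.loc[keep_ids].reset_index().rename(columns={"index": "subject_id"}), info
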