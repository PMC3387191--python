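"""SNP panel definitions: risk-allele coding and literature-OR weights.

A panel is an ordered set of biallelic SNPs, each oriented to its diabetes
risk allele and carrying a per-allele odds ratio taken from the literature.
The weight used by the weighted genetic risk score is ``w_i = ln(OR_i)``,
the per-allele effect on the log-odds scale, so weights are additive and a
SNP with OR 1 contributes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "SNPDescriptor",
    "SNPPanel",
    "PanelError",
    "load_panel",
    "default_panel",
    "secretion_subset",
]

_VALID_ALLELES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


@dataclass(frozen=True)
class SNPDescriptor:
    """One panel entry, oriented to the risk allele.

    Parameters
    ----------
    rsid : str
        dbSNP identifier, unique within a panel.
    gene : str
        Gene label (nearest/assigned locus), informational only.
    risk_allele : str
        Single nucleotide; dosages are counted on this allele.
    or_literature : float
        Per-allele odds ratio for type 2 diabetes, must be >= 1 after
        orientation to the risk allele.
    secretion_related : bool
        True if the locus primarily modulates insulin secretion; drives
        the 7-SNP secretion-restricted sub-panel.
    risk_allele_freq : float or None
        Optional population risk-allele frequency, used only by the
        synthetic-cohort generator.
    """

    rsid: str
    gene: str
    risk_allele: str
    or_literature: float
    secretion_related: bool
    risk_allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in _VALID_ALLELES:
            raise PanelError(
                f"{self.rsid}: risk allele must be one of A/C/G/T, got {self.risk_allele!r}"
            )
        if not (self.or_literature > 0):
            raise PanelError(f"{self.rsid}: odds ratio must be positive, got {self.or_literature}")
        if self.or_literature < 1.0:
            raise PanelError(
                f"{self.rsid}: OR {self.or_literature} < 1 — re-orient the row to the risk "
                "allele (flip the allele and invert the OR); ambiguous rows are refused"
            )
        if self.risk_allele_freq is not None and not (0.0 < self.risk_allele_freq < 1.0):
            raise PanelError(f"{self.rsid}: risk_allele_freq must lie in (0, 1)")

    @property
    def weight(self) -> float:
        """Per-allele log-odds weight, ``ln(OR)`` (0 for OR = 1)."""
        return math.log(self.or_literature)


@dataclass(frozen=True)
class SNPPanel:
    """Ordered collection of :class:`SNPDescriptor` with unique rsIDs."""

    snps: tuple[SNPDescriptor, ...]

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise PanelError("panel must contain at least one SNP")
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelError(f"duplicate rsid(s) in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def n(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def weights(self) -> list[float]:
        return [s.weight for s in self.snps]

    @property
    def risk_alleles(self) -> list[str]:
        return [s.risk_allele for s in self.snps]

    def get(self, rsid: str) -> SNPDescriptor:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "gene": [s.gene for s in self.snps],
                "risk_allele": self.risk_alleles,
                "or_literature": [s.or_literature for s in self.snps],
                "weight": self.weights,
                "secretion_related": [s.secretion_related for s in self.snps],
                "risk_allele_freq": [s.risk_allele_freq for s in self.snps],
            }
        )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise PanelError(f"cannot parse boolean panel field {value!r}")


def load_panel(path: str | Path) -> SNPPanel:
    """Load a panel from a delimited text file.

    The file is TSV (or comma-separated) with columns ``rsid``, ``gene``,
    ``risk_allele``, ``or_literature``, ``secretion_related`` and an
    optional ``risk_allele_freq``; ``#`` lines are comments. Row order is
    preserved. Rows with OR < 1 are refused with instructions to
    re-orient rather than silently flipped.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    required = {"rsid", "gene", "risk_allele", "or_literature", "secretion_related"}
    missing = required - set(df.columns)
    if missing:
        raise PanelError(f"panel file {path} is missing columns: {sorted(missing)}")
    snps = []
    for row in df.itertuples(index=False):
        freq = getattr(row, "risk_allele_freq", None)
        snps.append(
            SNPDescriptor(
                rsid=str(row.rsid).strip(),
                gene=str(row.gene).strip(),
                risk_allele=str(row.risk_allele).strip().upper(),
                or_literature=float(row.or_literature),
                secretion_related=_parse_bool(row.secretion_related),
                risk_allele_freq=None if freq is None or pd.isna(freq) else float(freq),
            )
        )
    return SNPPanel(tuple(snps))


def default_panel() -> SNPPanel:
    """The packaged default 9-SNP panel (editable literature defaults)."""
    with resources.as_file(
        resources.files("prediagrs.data").joinpath("default_panel.tsv")
    ) as p:
        return load_panel(p)


def secretion_subset(panel: SNPPanel) -> SNPPanel:
    """Sub-panel of SNPs flagged as primarily insulin-secretion related.

    For the default 9-SNP panel this drops the FTO and PPARG loci and
    returns the 7 secretion loci. Idempotent; an empty subset is an error.
    """
    kept = tuple(s for s in panel if s.secretion_related)
    if not kept:
        raise PanelError("secretion subset is empty: no SNP is flagged secretion_related")
    return SNPPanel(kept)
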