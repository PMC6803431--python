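"""Fixed-difference SNP calling between the parental GH cDNAs and
genotype verification at a called site.

The two parental lines are purebred (nine generations of selfing), so
every inter-parental difference in the cDNA is treated as a fixed
difference: the Nile allele is the maternal allele in the hybrid, the
blue allele the paternal one. Positions are reported in the signed CDS
coordinates of sequence A (the Nile-referenced cDNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import PairwiseAlignment
from .coords import index_to_signed, validate_coord
from .errors import IncompatibleGenotypeError, ValidationError

# IUPAC codes for the two-base ambiguities a Sanger trace can show.
_AMBIGUITY = {
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
}


@dataclass(frozen=True)
class SnpSite:
    """One fixed inter-parental difference."""

    position: int  # signed CDS coordinate
    nile_allele: str
    blue_allele: str

    def __post_init__(self) -> None:
        validate_coord(self.position)
        if self.nile_allele == self.blue_allele:
            raise ValidationError(f"site {self.position}: alleles must differ")


@dataclass(frozen=True)
class IndelColumn:
    """An alignment column with a gap; reported separately from SNPs."""

    position: int  # signed coordinate of the A base at or just 5' of the gap
    a_base: str
    b_base: str


@dataclass(frozen=True)
class GenotypeCall:
    individual: str
    site: SnpSite
    observed: frozenset
    zygosity: str  # "homozygous" | "heterozygous"


def call_fixed_differences(
    alignment: PairwiseAlignment, utr5_len: int = 26
) -> list[SnpSite]:
    """Substitution columns of a parental alignment as SNP sites.

    Gap columns are never emitted as SNPs; use :func:`indel_columns` for
    those.
    """
    sites: list[SnpSite] = []
    a_index = 0
    for base_a, base_b in alignment.columns():
        if base_a != "-":
            if base_b != "-" and base_a != base_b:
                sites.append(
                    SnpSite(index_to_signed(a_index, utr5_len), base_a, base_b)
                )
            a_index += 1
    return sites


def indel_columns(alignment: PairwiseAlignment, utr5_len: int = 26) -> list[IndelColumn]:
    """Gap columns of the alignment, positioned by the nearest A base."""
    cols: list[IndelColumn] = []
    a_index = 0
    for base_a, base_b in alignment.columns():
        if base_a == "-" or base_b == "-":
            anchor = a_index if base_a != "-" else max(a_index - 1, 0)
            cols.append(IndelColumn(index_to_signed(anchor, utr5_len), base_a, base_b))
        if base_a != "-":
            a_index += 1
    return cols


def normalize_observed(observed) -> frozenset:
    """Normalise trace evidence to a base set.

    Accepts a base, an IUPAC two-base ambiguity letter, or any iterable
    of bases.
    """
    if isinstance(observed, str):
        obs = observed.upper()
        if len(obs) == 1 and obs in _AMBIGUITY:
            return frozenset(_AMBIGUITY[obs])
        bases = frozenset(obs)
    else:
        bases = frozenset(str(b).upper() for b in observed)
    if not bases or not bases <= set("ACGT") or len(bases) > 2:
        raise ValidationError(f"observed bases must be 1-2 of ACGT, got {observed!r}")
    return bases


def genotype_at_site(observed, site: SnpSite, individual: str = "") -> GenotypeCall:
    """Classify Sanger evidence at a fixed-difference site.

    A single parental base is a homozygote of that parent's type; both
    parental bases together indicate the heterozygous hybrid.
    """
    bases = normalize_observed(observed)
    alleles = {site.nile_allele, site.blue_allele}
    if not bases <= alleles:
        raise IncompatibleGenotypeError(
            f"observed {set(bases)} incompatible with {site.nile_allele}/"
            f"{site.blue_allele} at position {site.position}"
        )
    zygosity = "heterozygous" if len(bases) == 2 else "homozygous"
    return GenotypeCall(individual, site, bases, zygosity)


def read_parental_fasta(path: str | Path) -> tuple[str, str]:
    """Read the two parental cDNA records (Nile first, blue second)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValidationError(f"expected 2 parental records, found {len(records)}")
    return str(records[0].seq), str(records[1].seq)


def write_parental_fasta(nile: str, blue: str, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(nile), id="GH_Nile", description="Nile tilapia GH cDNA (maternal)"),
        SeqRecord(Seq(blue), id="GH_blue", description="blue tilapia GH cDNA (paternal)"),
    ]
    SeqIO.write(records, str(path), "fasta")


def write_snp_report(sites: list[SnpSite], path: str | Path) -> None:
    pd.DataFrame(
        [(s.position, s.nile_allele, s.blue_allele) for s in sites],
        columns=["position", "allele_N", "allele_B"],
    ).to_csv(path, sep="\t", index=False)
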