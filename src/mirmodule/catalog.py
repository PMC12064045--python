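"""Mature miRNAs, seed families, and canonical 3'UTR seed-match sites.

A mature miRNA recognises a target mRNA mainly through its *seed*,
nucleotides 2-8 from the 5' end.  miRNAs with identical seeds are
functionally interchangeable on canonical sites and are grouped into a
single *seed family*, the counting unit for all downstream target-site
matrices.

Canonical site types on the mRNA sense strand (5'->3'):

``8mer``
    perfect Watson-Crick match to miRNA positions 2-8 plus an adenosine
    across from miRNA position 1 (the A1 is a literal ``A`` on the mRNA,
    independent of the miRNA's first base).
``7mer-m8``
    perfect match to miRNA positions 2-8.
``7mer-A1``
    perfect match to miRNA positions 2-7 plus the A1 adenosine.

Because the mRNA is antiparallel to the miRNA, a site is the reverse
complement of the seed region read on the mRNA sense strand, with the A1
position at the site's 3' end.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: site-type priority used whenever one locus admits several classifications
SITE_TYPE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1")

SITE_TYPE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7}


class AlphabetError(ValueError):
    """A sequence contains characters outside the declared alphabet."""


class SeedLengthError(ValueError):
    """A miRNA sequence is too short to carry a 7-nt seed."""


def _check_alphabet(sequence: str, alphabet: frozenset[str], what: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(
            f"{what} contains invalid characters {sorted(bad)}; "
            f"allowed: {sorted(alphabet)}"
        )
    return seq


def rna_to_dna(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def dna_to_rna(sequence: str) -> str:
    return sequence.upper().replace("T", "U")


def reverse_complement_dna(sequence: str) -> str:
    return sequence.translate(_DNA_COMPLEMENT)[::-1]


def extract_seed(sequence: str) -> str:
    """Return the 7-nt seed, miRNA positions 2-8 (1-based), of an RNA sequence."""
    seq = _check_alphabet(sequence, RNA_ALPHABET, "miRNA sequence")
    if len(seq) < 8:
        raise SeedLengthError(
            f"miRNA sequence of length {len(seq)} is shorter than 8 nt; "
            "cannot extract a 7-nt seed"
        )
    return seq[1:8]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA with its derived seed.

    ``family_id`` is assigned later by :func:`assign_families`; until then it
    defaults to the miRNA's own name (a singleton family).
    """

    name: str
    sequence: str
    family_id: str = ""

    def __post_init__(self) -> None:
        seq = _check_alphabet(self.sequence, RNA_ALPHABET, f"miRNA {self.name!r}")
        if not 18 <= len(seq) <= 26:
            raise ValueError(
                f"miRNA {self.name!r} has length {len(seq)}; expected 18-26 nt"
            )
        object.__setattr__(self, "sequence", seq)
        if not self.family_id:
            object.__setattr__(self, "family_id", self.name)

    @property
    def seed(self) -> str:
        return extract_seed(self.sequence)

    # -- site strings on the mRNA (DNA, sense strand, 5'->3') ---------------

    def site_string(self, site_type: str) -> str:
        """DNA string a canonical site of ``site_type`` reads on the mRNA."""
        seed_dna = rna_to_dna(self.seed)           # miRNA 2-8
        core7 = reverse_complement_dna(seed_dna)   # matches miRNA 2-8
        core6 = reverse_complement_dna(seed_dna[:6])  # matches miRNA 2-7
        if site_type == "8mer":
            return core7 + "A"
        if site_type == "7mer-m8":
            return core7
        if site_type == "7mer-A1":
            return core6 + "A"
        raise ValueError(f"unknown site type {site_type!r}")


@dataclass(frozen=True)
class SiteMatch:
    """One canonical seed-match locus on a 3'UTR (1-based inclusive)."""

    gene: str
    site_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPE_LENGTH:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start + 1 != SITE_TYPE_LENGTH[self.site_type]:
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with {self.site_type}"
            )


def assign_families(mirnas: Sequence[MatureMiRNA]) -> dict[str, str]:
    """Group miRNAs by identical seed; return name -> family_id.

    The family identifier is deterministic: the lexicographically smallest
    member name, joined with ``"/"`` to the remaining members in sorted order
    (e.g. ``"miR-279-3p/miR-996-3p"``).
    """
    names = [m.name for m in mirnas]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate miRNA names: {dupes}")
    by_seed: dict[str, list[str]] = {}
    for m in mirnas:
        by_seed.setdefault(m.seed, []).append(m.name)
    assignment: dict[str, str] = {}
    for members in by_seed.values():
        family_id = "/".join(sorted(members))
        for name in members:
            assignment[name] = family_id
    return assignment


def apply_families(mirnas: Sequence[MatureMiRNA]) -> list[MatureMiRNA]:
    """Return copies of ``mirnas`` with ``family_id`` filled in."""
    assignment = assign_families(mirnas)
    return [
        MatureMiRNA(m.name, m.sequence, family_id=assignment[m.name]) for m in mirnas
    ]


def scan_utr_sites(utr: str, mirna: MatureMiRNA, gene: str = "") -> list[SiteMatch]:
    """Scan a 3'UTR (DNA sense strand) for canonical sites of one miRNA.

    The scan moves left to right; at each position the best site type
    starting there is taken (8mer > 7mer-m8 > 7mer-A1) and the cursor jumps
    past it, so counted sites never overlap and every locus carries exactly
    one type.  Coordinates are 1-based inclusive.
    """
    if utr == "":
        return []
    seq = _check_alphabet(utr, DNA_ALPHABET, f"3'UTR {gene!r}" if gene else "3'UTR")
    patterns = [(t, mirna.site_string(t)) for t in SITE_TYPE_PRIORITY]
    matches: list[SiteMatch] = []
    i = 0
    n = len(seq)
    while i < n:
        hit = None
        for site_type, pattern in patterns:
            if seq.startswith(pattern, i):
                hit = (site_type, len(pattern))
                break
        if hit is None:
            i += 1
        else:
            site_type, length = hit
            matches.append(SiteMatch(gene, site_type, i + 1, i + length))
            i += length
    return matches


def count_sites(utr: str, mirna: MatureMiRNA) -> int:
    return len(scan_utr_sites(utr, mirna))


# ---------------------------------------------------------------------------
# prediction-table readers
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = ("gene", "family", "site_type", "start", "end")


@dataclass
class PredictionRecord:
    """One (family, gene) record from an external prediction source."""

    family_id: str
    gene: str
    site_count: int
    sites: list[SiteMatch] = field(default_factory=list)


class PredictionFormatError(ValueError):
    """A prediction file is missing mandatory columns or is malformed."""


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_predictions(path: str | Path, dialect: str) -> list[PredictionRecord]:
    """Read miRNA-family -> gene target predictions.

    Two dialects are supported, both headered TSV tolerating CRLF line ends
    and ``#`` comment lines:

    ``site_table``
        columns (gene, family, site_type, start, end), one row per site.
    ``count_matrix``
        genes as rows (first column), seed families as remaining columns,
        cells holding non-negative site counts -- the layout of a deposited
        gene-by-family matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "site_table":
        return _read_site_table(path)
    if dialect == "count_matrix":
        return _read_count_matrix(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'site_table' or 'count_matrix'")


def _read_site_table(path: Path) -> list[PredictionRecord]:
    df = _read_tsv(path)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PredictionFormatError(f"{path}: missing mandatory columns {missing}")
    extra = [c for c in df.columns if c not in SITE_TABLE_COLUMNS]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    records: dict[tuple[str, str], PredictionRecord] = {}
    for row in df.itertuples(index=False):
        site = SiteMatch(row.gene, row.site_type, int(row.start), int(row.end))
        key = (row.family, row.gene)
        rec = records.get(key)
        if rec is None:
            rec = records[key] = PredictionRecord(row.family, row.gene, 0)
        rec.sites.append(site)
        rec.site_count += 1
    return list(records.values())


def _read_count_matrix(path: Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.empty and df.columns.empty:
        raise PredictionFormatError(f"{path}: no family columns found")
    records: list[PredictionRecord] = []
    for gene, row in df.iterrows():
        for family, value in row.items():
            count = float(value)
            if count < 0:
                raise ValueError(
                    f"{path}: negative site count {value!r} for gene {gene!r}, "
                    f"family {family!r}"
                )
            if count != int(count):
                raise ValueError(
                    f"{path}: non-integer site count {value!r} for gene {gene!r}"
                )
            if count > 0:
                records.append(PredictionRecord(str(family), str(gene), int(count)))
    return records


# ---------------------------------------------------------------------------
# FASTA IO (RNA for miRNAs, DNA for UTRs)
# ---------------------------------------------------------------------------

def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read mature miRNAs (RNA alphabet) from FASTA and assign seed families."""
    from Bio import SeqIO

    mirnas = []
    seen: set[str] = set()
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"{path}: duplicate miRNA id {record.id!r}")
            seen.add(record.id)
            mirnas.append(MatureMiRNA(record.id, dna_to_rna(str(record.seq))))
    return apply_families(mirnas)


def read_utr_fasta(path: str | Path) -> dict[str, str]:
    """Read 3'UTR sequences (DNA sense strand) from FASTA."""
    from Bio import SeqIO

    utrs: dict[str, str] = {}
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in utrs:
                raise ValueError(f"{path}: duplicate gene id {record.id!r}")
            utrs[record.id] = _check_alphabet(
                str(record.seq), DNA_ALPHABET, f"3'UTR {record.id!r}"
            )
    return utrs
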