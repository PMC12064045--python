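"""Design of miRNA sponge and multi-sponge knockdown constructs.

A sponge transgene carries tandem miRNA binding sites in a reporter
3'UTR.  Each site is the reverse complement of the target miRNA (so the
miRNA binds with full seed pairing) except for four mismatches across
from miRNA positions 9-12: the central bulge prevents Argonaute-
catalysed slicing, so the sponge sequesters the miRNA instead of being
degraded.  The default construct is 20 site repeats separated by
variable 4-nt linkers; for a 21-nt miRNA that is 20*21 + 19*4 = 496 nt.
Linkers are drawn pseudo-randomly from a seed and redrawn whenever the
junction they create would form a new canonical seed site for the
target miRNA.  Multi-sponges against a subgroup of miRNAs are the
concatenation of single cassettes with one linker between them.

The default mismatch substitution (miRNA base -> site base) is
A->C, U->C, G->A, C->A: each substituted site base can neither
Watson-Crick pair nor G:U wobble pair with its miRNA counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import MatureMiRNA, reverse_complement_dna, rna_to_dna

__all__ = [
    "DEFAULT_MISMATCH_TABLE",
    "MISMATCH_WINDOW",
    "Annotation",
    "SpongeCassette",
    "design_site",
    "assemble_cassette",
    "assemble_multisponge",
    "audit_complementarity",
    "write_fasta",
    "write_feature_table",
]

#: miRNA positions (1-based) left unpaired in the sponge site
MISMATCH_WINDOW = (9, 10, 11, 12)

#: miRNA base -> substituted site base (no Watson-Crick, no G:U wobble)
DEFAULT_MISMATCH_TABLE: dict[str, str] = {"A": "C", "U": "C", "G": "A", "C": "A"}

_WATSON_CRICK = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("U", "G")}  # (miRNA base, site DNA base)


@dataclass(frozen=True)
class Annotation:
    """One annotated feature of a construct, 1-based inclusive."""

    feature: str  # "misc_binding" for sites, "misc_feature" for linkers
    label: str
    start: int
    end: int

    def shifted(self, offset: int) -> "Annotation":
        return Annotation(self.feature, self.label, self.start + offset, self.end + offset)


@dataclass
class SpongeCassette:
    """A (multi-)sponge construct: sequence plus feature annotations."""

    name: str
    mirna_names: list[str]
    sites: dict[str, str]  # miRNA name -> its designed site
    n_repeats: int
    linkers: list[str]
    full_sequence: str
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.annotations:
            span = self.full_sequence[ann.start - 1 : ann.end]
            if ann.feature == "misc_binding" and span not in self.sites.values():
                raise ValueError(
                    f"annotation {ann.label!r} span does not equal a designed site"
                )

    def site_spans(self) -> list[tuple[int, int]]:
        return [
            (a.start, a.end) for a in self.annotations if a.feature == "misc_binding"
        ]


def design_site(
    mirna: MatureMiRNA, mismatch_table: Mapping[str, str] | None = None
) -> str:
    """Design one binding site (DNA, mRNA sense strand) for a miRNA.

    The site is the reverse complement of the miRNA except at the four
    positions pairing miRNA 9-12 (site positions L-11..L-8 for miRNA
    length L), which are substituted via ``mismatch_table``.
    """
    table = dict(mismatch_table or DEFAULT_MISMATCH_TABLE)
    if set(table) != set("ACGU") or any(v not in "ACGT" for v in table.values()):
        raise ValueError(
            "mismatch table must map every RNA base A/C/G/U to a DNA base"
        )
    seq = mirna.sequence
    length = len(seq)
    site = list(reverse_complement_dna(rna_to_dna(seq)))
    for mirna_pos in MISMATCH_WINDOW:
        site_pos = length + 1 - mirna_pos  # 1-based on the site
        site[site_pos - 1] = table[seq[mirna_pos - 1]]
    return "".join(site)


def audit_complementarity(site: str, mirna: MatureMiRNA) -> list[int]:
    """miRNA positions (1-based) NOT Watson-Crick paired in the site.

    The site is aligned antiparallel: site position j pairs miRNA
    position L+1-j.
    """
    seq = mirna.sequence
    if len(site) != len(seq):
        raise ValueError("site and miRNA lengths differ")
    mismatched = []
    for mirna_pos in range(1, len(seq) + 1):
        site_base = site[len(seq) - mirna_pos]
        if (seq[mirna_pos - 1], site_base) not in _WATSON_CRICK:
            mismatched.append(mirna_pos)
    return mismatched


def pairs_or_wobbles(mirna_base: str, site_base: str) -> bool:
    pair = (mirna_base, site_base)
    return pair in _WATSON_CRICK or pair in _WOBBLE


def _junction_creates_site(
    prev_tail: str, linker: str, next_head: str, mirnas: Sequence[MatureMiRNA]
) -> bool:
    """True if inserting ``linker`` creates a canonical site overlapping it."""
    window = prev_tail + linker + next_head
    lo, hi = len(prev_tail), len(prev_tail) + len(linker)  # linker half-open span
    for mirna in mirnas:
        for site_type in ("8mer", "7mer-m8", "7mer-A1"):
            pattern = mirna.site_string(site_type)
            start = window.find(pattern)
            while start != -1:
                end = start + len(pattern)
                if start < hi and end > lo:  # overlaps the linker
                    return True
                start = window.find(pattern, start + 1)
    return False


def _draw_linker(
    rng: np.random.Generator,
    prev_tail: str,
    next_head: str,
    mirnas: Sequence[MatureMiRNA],
    length: int = 4,
    max_redraws: int = 100,
) -> str:
    for _ in range(max_redraws):
        linker = "".join(rng.choice(list("ACGT"), size=length))
        if not _junction_creates_site(prev_tail, linker, next_head, mirnas):
            return linker
    raise RuntimeError(
        f"could not draw a junction-safe {length}-nt linker in {max_redraws} tries"
    )


def assemble_cassette(
    mirna: MatureMiRNA,
    n_repeats: int = 20,
    seed: int = 0,
    mismatch_table: Mapping[str, str] | None = None,
    linker_length: int = 4,
    max_redraws: int = 100,
) -> SpongeCassette:
    """Tandem sponge cassette: ``n_repeats`` sites with seeded linkers."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    site = design_site(mirna, mismatch_table)
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    annotations: list[Annotation] = []
    linkers: list[str] = []
    pos = 0  # 0-based running length
    flank = max(len(site), 8)
    for repeat in range(n_repeats):
        if repeat > 0:
            linker = _draw_linker(
                rng, pieces[-1][-flank:], site[:flank], [mirna], linker_length, max_redraws
            )
            linkers.append(linker)
            pieces.append(linker)
            annotations.append(
                Annotation("misc_feature", f"linker_{repeat}", pos + 1, pos + len(linker))
            )
            pos += len(linker)
        pieces.append(site)
        annotations.append(
            Annotation(
                "misc_binding",
                f"{mirna.name}_site_{repeat + 1}",
                pos + 1,
                pos + len(site),
            )
        )
        pos += len(site)
    return SpongeCassette(
        name=f"{mirna.name}-sponge",
        mirna_names=[mirna.name],
        sites={mirna.name: site},
        n_repeats=n_repeats,
        linkers=linkers,
        full_sequence="".join(pieces),
        annotations=annotations,
    )


def assemble_multisponge(
    cassettes: Sequence[SpongeCassette],
    mirnas: Mapping[str, MatureMiRNA] | None = None,
    seed: int = 0,
    linker_length: int = 4,
    max_redraws: int = 100,
) -> SpongeCassette:
    """Concatenate single cassettes with one linker between each pair."""
    if len(cassettes) < 2:
        raise ValueError("a multi-sponge needs at least 2 member cassettes")
    mirnas = dict(mirnas or {})
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    annotations: list[Annotation] = []
    linkers: list[str] = []
    sites: dict[str, str] = {}
    names: list[str] = []
    pos = 0
    for idx, cassette in enumerate(cassettes):
        if idx > 0:
            guard = [
                mirnas[n]
                for n in (*cassettes[idx - 1].mirna_names, *cassette.mirna_names)
                if n in mirnas
            ]
            linker = _draw_linker(
                rng,
                pieces[-1][-30:],
                cassette.full_sequence[:30],
                guard,
                linker_length,
                max_redraws,
            )
            linkers.append(linker)
            pieces.append(linker)
            annotations.append(
                Annotation(
                    "misc_feature", f"cassette_linker_{idx}", pos + 1, pos + len(linker)
                )
            )
            pos += len(linker)
        pieces.append(cassette.full_sequence)
        annotations.extend(a.shifted(pos) for a in cassette.annotations)
        pos += len(cassette.full_sequence)
        sites.update(cassette.sites)
        names.extend(cassette.mirna_names)
        linkers.extend(cassette.linkers)
    return SpongeCassette(
        name="+".join(c.name for c in cassettes),
        mirna_names=names,
        sites=sites,
        n_repeats=sum(c.n_repeats for c in cassettes),
        linkers=linkers,
        full_sequence="".join(pieces),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_fasta(cassette: SpongeCassette, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(
        Seq(cassette.full_sequence),
        id=cassette.name,
        description=f"{cassette.n_repeats} binding sites; "
        f"targets {','.join(cassette.mirna_names)}",
    )
    seqio_write([record], str(path), "fasta")


def write_feature_table(cassette: SpongeCassette, path: str | Path) -> None:
    """GenBank-style five-column feature table (tab separated)."""
    lines = [f">Feature {cassette.name}"]
    for ann in cassette.annotations:
        lines.append(f"{ann.start}\t{ann.end}\t{ann.feature}")
        lines.append(f"\t\t\tnote\t{ann.label}")
    Path(path).write_text("\n".join(lines) + "\n")
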