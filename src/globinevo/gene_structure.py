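"""Intron positions in globin helix coordinates and exon-structure projection.

Globin intron positions are conventionally written as ``<helix><codon>.<phase>``:
"B12.2" is an intron between the second and third base of codon 12 of helix B.
Phase-0 codes number the downstream codon ("G7.0" = intron immediately before
helix-G codon 7), the standard usage in the globin literature. Introns at
B12.2 and G7.0 are the phylogenetically ancient globin introns; vertebrate
neuroglobin carries an extra central intron at E11.0, urochordate globins at
E10.2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seqio import GeneModel
from .synthetic import HelixAnnotation

_CODE_RE = re.compile(r"^([A-Z]+?)(\d+)\.([012])$")


@dataclass(frozen=True)
class IntronCode:
    segment: str
    codon_index: int
    phase: int

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0, 1 or 2, got {self.phase}")
        if self.codon_index < 1:
            raise ValueError("codon_index is 1-based")

    def __str__(self) -> str:
        return f"{self.segment}{self.codon_index}.{self.phase}"

    @classmethod
    def parse(cls, text: str) -> "IntronCode":
        m = _CODE_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse intron code {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


def cds_offset_to_code(offset_nt: int, cds_length: int, helices: HelixAnnotation) -> IntronCode:
    """Helix-coordinate code for an intron immediately after CDS base ``offset_nt``."""
    if not (1 <= offset_nt <= cds_length - 1):
        raise ValueError(
            f"intron junction at CDS offset {offset_nt} outside the coding "
            f"region (valid range 1..{cds_length - 1})"
        )
    phase = offset_nt % 3
    # phase 0: the code names the downstream codon; phase 1/2: the codon the
    # intron interrupts — both reduce to floor(offset/3) + 1
    residue = offset_nt // 3 + 1
    segment, codon_index = helices.segment_of(residue)
    return IntronCode(segment, codon_index, phase)


def intron_code_to_cds_offset(code: IntronCode | str, helices: HelixAnnotation) -> int:
    """CDS nucleotide offset (bases 5' of the intron) encoded by a helix code."""
    if isinstance(code, str):
        code = IntronCode.parse(code)
    residue = helices.residue_of(code.segment, code.codon_index)
    return (residue - 1) * 3 + code.phase


def map_intron_to_helix_code(gene: GeneModel, helices: HelixAnnotation) -> list[IntronCode]:
    """Helix-coordinate codes for every junction between consecutive CDS intervals."""
    cds_length = gene.cds_length
    if cds_length // 3 > helices.protein_length:
        raise ValueError(
            f"{gene.gene_id}: CDS encodes {cds_length // 3} residues but helix "
            f"annotation covers only {helices.protein_length}"
        )
    return [
        cds_offset_to_code(offset, cds_length, helices)
        for offset in gene.cds_junction_offsets()
    ]


ANCESTRAL_CODES = {"B12.2", "G7.0"}
CENTRAL_SEGMENTS = {"E", "DE", "EF"}


def classify_intron_codes(codes: list[IntronCode | str]) -> list[str]:
    """Classify each intron as "ancestral" (the ancient B12.2/G7.0 globin
    introns), "central" (inside helix E or its flanking linkers), or "other"."""
    out = []
    for code in codes:
        if isinstance(code, str):
            code = IntronCode.parse(code)
        if str(code) in ANCESTRAL_CODES:
            out.append("ancestral")
        elif code.segment in CENTRAL_SEGMENTS:
            out.append("central")
        else:
            out.append("other")
    return out


@dataclass
class ExonProjection:
    """Per-row exon indices along protein alignment columns (None at gaps)."""

    taxa: list[str]
    rows: dict[str, list[int | None]]

    def render_text(self) -> str:
        lines = []
        for taxon in self.taxa:
            cells = "".join(
                "-" if x is None else (str(x) if x < 10 else "*")
                for x in self.rows[taxon]
            )
            lines.append(f"{taxon}\t{cells}")
        return "\n".join(lines) + "\n"


def _exon_index_per_residue(gene: GeneModel) -> list[int]:
    """1-based coding-exon index for each protein residue.

    A residue split by a phase-1/2 intron belongs to the exon containing the
    codon's first base.
    """
    lengths = [b - a for a, b in gene.cds]
    n_res = sum(lengths) // 3
    boundaries = []
    total = 0
    for ln in lengths:
        total += ln
        boundaries.append(total)
    out = []
    exon = 0
    for r in range(1, n_res + 1):
        first_base = (r - 1) * 3  # 0-based CDS offset of the codon's first base
        while first_base >= boundaries[exon]:
            exon += 1
        out.append(exon + 1)
    return out


def project_exon_structure(
    genes: list[GeneModel], protein_alignment: dict[str, str]
) -> ExonProjection:
    """Project each gene's coding-exon structure onto a protein alignment."""
    by_id = {g.gene_id: g for g in genes}
    taxa = [g.gene_id for g in genes if g.gene_id in protein_alignment]
    missing = [g.gene_id for g in genes if g.gene_id not in protein_alignment]
    if missing:
        raise ValueError(f"genes absent from alignment: {missing}")
    rows: dict[str, list[int | None]] = {}
    for taxon in taxa:
        gene = by_id[taxon]
        aligned = protein_alignment[taxon]
        n_res = sum(b - a for a, b in gene.cds) // 3
        ungapped = len(aligned) - aligned.count("-")
        if ungapped != n_res:
            raise ValueError(
                f"{taxon}: alignment row has {ungapped} residues but CDS "
                f"encodes {n_res}"
            )
        per_res = _exon_index_per_residue(gene)
        row: list[int | None] = []
        ri = 0
        for ch in aligned:
            if ch == "-":
                row.append(None)
            else:
                row.append(per_res[ri])
                ri += 1
        rows[taxon] = row
    return ExonProjection(taxa, rows)
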