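"""Readers and writers for the plain-text formats the pipeline touches.

Internally all coordinates are 0-based half-open in scaffold space; GFF input
and output converts from/to the 1-based closed convention at the boundary.
Gene models are normalised to transcript orientation (minus-strand exon lists
run 5'→3' along the transcript, i.e. descending scaffold coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("globinevo")

DNA_ALPHABET = set("ACGTRYSWKMBDHVN-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBJZXUO*-")


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence with a declared molecule type.

    Sequences are stored uppercase and validated against the IUPAC alphabet
    of the declared ``moltype`` (gap characters allowed, for alignments).
    """

    id: str
    seq: str
    moltype: str = "dna"

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        alphabet = DNA_ALPHABET if self.moltype == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} outside the "
                f"{self.moltype} IUPAC alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate an ungapped CDS (standard code); trailing stop dropped."""
    aa = str(Seq(cds).translate())
    return aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, moltype: str = "dna") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects (order preserved)."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, str(rec.seq), moltype))
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """Strand-aware exon/CDS/TSS/TIS coordinates on a named scaffold.

    ``exons`` and ``cds`` are ``[start, end)`` scaffold intervals listed in
    transcript orientation. ``tss``/``tis`` are the scaffold positions of the
    first transcribed base and of the A of the start codon.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    tss: int
    tis: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = [tuple(x) for x in self.exons]
        self.cds = [tuple(x) for x in self.cds]
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for a, b in ivs:
                if a >= b:
                    raise ValueError(f"{self.gene_id}: empty {name} interval {a, b}")
            by_start = sorted(ivs)
            for (a1, b1), (a2, b2) in zip(by_start, by_start[1:]):
                if b1 > a2:
                    raise ValueError(f"{self.gene_id}: overlapping {name} intervals")
        expect = sorted(self.exons, reverse=self.strand == "-")
        if self.exons != expect:
            raise ValueError(
                f"{self.gene_id}: exons not in transcript orientation"
            )
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError(f"{self.gene_id}: CDS interval {a, b} outside exons")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if self.cds:
            first = self.cds[0]
            if not (first[0] <= self.tis < first[1]):
                raise ValueError(f"{self.gene_id}: TIS not inside first CDS interval")

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def utr5_length(self) -> int:
        """Length of the (contiguous) 5'UTR between TSS and TIS."""
        return (self.tis - self.tss) if self.strand == "+" else (self.tss - self.tis)

    def span(self) -> tuple[int, int]:
        """Scaffold footprint [start, end) of all exons."""
        starts = [a for a, _ in self.exons]
        ends = [b for _, b in self.exons]
        return min(starts), max(ends)

    def cds_sequence(self, scaffold_seq: str) -> str:
        parts = []
        for a, b in self.cds:
            piece = scaffold_seq[a:b]
            parts.append(revcomp(piece) if self.strand == "-" else piece)
        return "".join(parts)

    def cds_junction_offsets(self) -> list[int]:
        """CDS-relative nucleotide offsets of intron junctions (bases 5' of each)."""
        offsets, total = [], 0
        for a, b in self.cds[:-1]:
            total += b - a
            offsets.append(total)
        return offsets


def read_gene_models(path) -> list[GeneModel]:
    """Parse a minimal GFF3 subset (gene/mRNA/exon/CDS, ID/Parent attributes).

    Unknown feature types are ignored with a warning. Exon/CDS features may be
    parented to the mRNA or directly to the gene.
    """
    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            if ftype == "gene":
                gid = attr.get("ID", f"gene{ln}")
                genes[gid] = {"scaffold": seqid, "strand": strand, "exon": [], "CDS": []}
                order.append(gid)
            elif ftype == "mRNA":
                parent_of[attr.get("ID", f"mrna{ln}")] = attr.get("Parent", "")
            elif ftype in ("exon", "CDS"):
                parent = attr.get("Parent", "")
                gid = parent_of.get(parent, parent)
                if gid not in genes:
                    raise ValueError(f"{path}:{ln}: {ftype} with unknown parent {parent!r}")
                genes[gid][ftype].append(iv)
            else:
                logger.warning("%s:%d: ignoring feature type %r", path, ln, ftype)
    models = []
    for gid in order:
        g = genes[gid]
        minus = g["strand"] == "-"
        exons = sorted(g["exon"], reverse=minus)
        cds = sorted(g["CDS"], reverse=minus)
        if not exons:
            exons = cds
        if sum(b - a for a, b in cds) % 3 != 0:
            raise ValueError(f"gene {gid}: CDS length not divisible by 3")
        tss = exons[0][0] if not minus else exons[0][1] - 1
        tis = cds[0][0] if not minus else cds[0][1] - 1
        models.append(GeneModel(gid, g["scaffold"], g["strand"], exons, cds, tss, tis))
    return models


def write_gene_models(models: Sequence[GeneModel], path, source: str = "globinevo") -> None:
    """Write gene models as the GFF3 subset read by :func:`read_gene_models`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span()
            fh.write(
                "\t".join(
                    [m.scaffold, source, "gene", str(span[0] + 1), str(span[1]),
                     ".", m.strand, ".", f"ID={m.gene_id}"]
                ) + "\n"
            )
            mrna = f"{m.gene_id}.t1"
            fh.write(
                "\t".join(
                    [m.scaffold, source, "mRNA", str(span[0] + 1), str(span[1]),
                     ".", m.strand, ".", f"ID={mrna};Parent={m.gene_id}"]
                ) + "\n"
            )
            for ftype, ivs in (("exon", m.exons), ("CDS", m.cds)):
                for a, b in sorted(ivs):
                    fh.write(
                        "\t".join(
                            [m.scaffold, source, ftype, str(a + 1), str(b),
                             ".", m.strand, ".", f"Parent={mrna}"]
                        ) + "\n"
                    )


# ---------------------------------------------------------------------------
# BED6 output for motif/TFBS hits


def write_bed6(rows: Iterable[tuple[str, int, int, str, float, str]], path) -> None:
    """Write (scaffold, start, end, name, score, strand) rows as BED6.

    Scores are scaled by 1000 and truncated to int, per the UCSC habit of
    packing a [0,1] score into the 0-1000 BED score column.
    """
    with open(path, "w") as fh:
        for scaf, start, end, name, score, strand in rows:
            fh.write(f"{scaf}\t{start}\t{end}\t{name}\t{int(score * 1000)}\t{strand}\n")
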