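"""Standard genetic code tables shared by the simulator and Ka/Ks counting."""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
ALL_CODONS = ["".join(p) for p in product(BASES, repeat=3)]
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
AA_OF = dict(standard_dna_table.forward_table)  # sense codons only

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    return TRANSITIONS.get(a) == b


def codons_of(cds: str) -> list[str]:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def contains_stop(cds: str) -> bool:
    return any(is_stop(c) for c in codons_of(cds))
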