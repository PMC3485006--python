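"""Synthetic-data generators: species trees, codon evolution under a target
dN/dS, promoter families with planted motifs, and multi-species loci with
anchor-gene neighbourhoods around a globin gene.

Every generator is a pure function of (configuration, seed). The canonical
globin fixture — a frozen 150-codon gene with a fixed helix annotation — is
the substrate for all intron-code worked examples.

The codon simulator works at the nucleotide-attempt level: mutation attempts
are Poisson in branch length × sequence length, target bases are drawn with
transition/transversion weighting (kappa), synonymous changes are always
accepted, nonsynonymous changes are accepted with probability min(1, omega),
and changes creating stop codons are rejected outright. This is simpler than
a full codon-matrix CTMC but reproduces the dN/dS signal the downstream
Nei–Gojobori estimator is asked to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codons import AA_OF, SENSE_CODONS, contains_stop, is_stop
from .seqio import GeneModel, SeqRecord, revcomp
from .trees import label_internal_nodes, node_name

BASES = "ACGT"

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# ---------------------------------------------------------------------------
# Species trees


def make_species_tree(
    n_taxa: int, mean_branch_length: float = 0.1, seed: int = 0
) -> dendropy.Tree:
    """Random bifurcating topology (uniform sequential joins) with i.i.d.
    exponential branch lengths."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = [f"sp{i + 1}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(taxa)
    nodes = []
    for t in taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.exponential(mean_branch_length))
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Codon evolution


@dataclass(frozen=True)
class CodonEvolutionConfig:
    omega: float = 0.2
    kappa: float = 2.0
    length_codons: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.omega < 0 or self.kappa < 0:
            raise ValueError("omega and kappa must be >= 0")
        if self.length_codons <= 0:
            raise ValueError("length_codons must be > 0")


def random_cds(n_codons: int, seed: int = 0) -> str:
    """Uniformly random CDS over the 61 sense codons (no stops)."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutate_along_branch(
    cds: list[str], branch_length: float, omega: float, kappa: float,
    rng: np.random.Generator,
) -> tuple[list[str], int, int]:
    """Apply Poisson(branch_length × length) mutation attempts to a CDS.

    Returns (sequence, accepted synonymous, accepted nonsynonymous).
    """
    seq = list(cds)
    n = len(seq)
    attempts = rng.poisson(branch_length * n)
    acc_syn = acc_non = 0
    for _ in range(attempts):
        site = int(rng.integers(0, n))
        base = seq[site]
        others = [b for b in BASES if b != base]
        weights = np.array(
            [kappa if b == _TRANSITION[base] else 1.0 for b in others]
        )
        total = weights.sum()
        if total == 0:
            continue
        target = others[int(rng.choice(3, p=weights / total))]
        codon_i, pos = divmod(site, 3)
        old_codon = "".join(seq[codon_i * 3 : codon_i * 3 + 3])
        new_codon = old_codon[:pos] + target + old_codon[pos + 1 :]
        if is_stop(new_codon):
            continue
        if AA_OF[old_codon] == AA_OF[new_codon]:
            seq[site] = target
            acc_syn += 1
        elif rng.random() < min(1.0, omega):
            seq[site] = target
            acc_non += 1
    return seq, acc_syn, acc_non


def simulate_codon_evolution(
    root_cds: str, tree: dendropy.Tree, config: CodonEvolutionConfig
) -> tuple[dict[str, str], dict[str, str]]:
    """Evolve ``root_cds`` down ``tree``; returns (leaf alignment, true ancestors).

    Internal nodes are labelled anc1, anc2, ... in preorder (the root is anc1
    unless already labelled), matching the labelling used by the parsimony
    reconstruction so simulated and inferred ancestors can be compared.
    """
    if len(root_cds) % 3:
        raise ValueError("root CDS length not divisible by 3")
    if contains_stop(root_cds):
        raise ValueError("root CDS contains a stop codon")
    rng = np.random.default_rng(config.seed)
    label_internal_nodes(tree)
    seqs: dict[int, list[str]] = {id(tree.seed_node): list(root_cds.upper())}
    leaves: dict[str, str] = {}
    ancestors: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = seqs[id(node)]
        else:
            parent_seq = seqs[id(node.parent_node)]
            current, _, _ = _mutate_along_branch(
                parent_seq, node.edge.length or 0.0, config.omega, config.kappa, rng
            )
            seqs[id(node)] = current
        if node.is_leaf():
            leaves[node.taxon.label] = "".join(current)
        else:
            ancestors[node_name(node)] = "".join(current)
    return leaves, ancestors


# ---------------------------------------------------------------------------
# Promoter families with planted motifs


@dataclass(frozen=True)
class MotifSpec:
    """A motif planted upstream of the TIS with positional jitter and bounded
    per-branch divergence along the species tree."""

    consensus: str
    offset_from_tis: int
    jitter_bp: int = 0
    max_mutations_per_branch: int = 0
    max_total_mutations: int | None = None
    name: str = ""

    def __post_init__(self):
        if self.offset_from_tis >= 0:
            raise ValueError("offset_from_tis must be negative (upstream)")
        if self.jitter_bp < 0 or self.max_mutations_per_branch < 0:
            raise ValueError("jitter_bp and max_mutations_per_branch must be >= 0")
        bad = set(self.consensus.upper()) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"invalid IUPAC symbols in consensus: {sorted(bad)}")

    @property
    def label(self) -> str:
        return self.name or self.consensus


@dataclass(frozen=True)
class PlantedSite:
    taxon: str
    motif: str
    offset_from_tis: int
    instance: str


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        s if s in BASES else IUPAC_DNA[s][int(rng.integers(0, len(IUPAC_DNA[s])))]
        for s in consensus.upper()
    )


def plant_promoter_family(
    tree: dendropy.Tree,
    length_bp: int,
    motif_specs: list[MotifSpec],
    gc_content: float = 0.4,
    seed: int = 0,
) -> tuple[dict[str, SeqRecord], list[PlantedSite]]:
    """Per-taxon promoter sequences (TIS-relative positions −length_bp…−1)
    with motif instances planted under jitter and per-branch mutation limits.

    Returns (records keyed by taxon, ground-truth planted sites).
    """
    rng = np.random.default_rng(seed)
    for spec in motif_specs:
        if not (-length_bp <= spec.offset_from_tis <= -len(spec.consensus)):
            raise ValueError(
                f"motif {spec.label}: offset {spec.offset_from_tis} does not fit "
                f"inside [-{length_bp}, -1]"
            )
    p_gc = gc_content / 2.0
    probs = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])  # A C G T

    # Evolve each motif instance down the tree, then jitter per taxon.
    instance_at: dict[int, dict[int, str]] = {}  # spec idx -> node id -> instance
    for si, spec in enumerate(motif_specs):
        root_instance = _realize_consensus(spec.consensus, rng)
        per_node = {id(tree.seed_node): root_instance}
        remaining = spec.max_total_mutations  # tree-wide budget (None = no cap)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = per_node[id(node.parent_node)]
            cap = spec.max_mutations_per_branch
            if remaining is not None:
                cap = min(cap, remaining)
            n_mut = int(rng.integers(0, cap + 1)) if cap > 0 else 0
            if remaining is not None:
                remaining -= n_mut
            inst = list(parent)
            for pos in rng.choice(len(inst), size=min(n_mut, len(inst)), replace=False):
                inst[pos] = [b for b in BASES if b != inst[pos]][int(rng.integers(0, 3))]
            per_node[id(node)] = "".join(inst)
        instance_at[si] = per_node

    records: dict[str, SeqRecord] = {}
    truth: list[PlantedSite] = []
    for leaf in tree.leaf_node_iter():
        taxon = leaf.taxon.label
        bg = rng.choice(list(BASES), size=length_bp, p=probs)
        seq = list("".join(bg))
        placed: list[tuple[int, int]] = []
        for si, spec in enumerate(motif_specs):
            inst = instance_at[si][id(leaf)]
            jitter = int(rng.integers(-spec.jitter_bp, spec.jitter_bp + 1)) if spec.jitter_bp else 0
            offset = spec.offset_from_tis + jitter
            offset = max(-length_bp, min(offset, -len(inst)))
            start = length_bp + offset
            end = start + len(inst)
            for a, b in placed:
                if start < b and a < end:
                    raise ValueError(
                        f"planted motifs overlap in taxon {taxon} at offset {offset}"
                    )
            placed.append((start, end))
            seq[start:end] = list(inst)
            truth.append(PlantedSite(taxon, spec.label, offset, inst))
        records[taxon] = SeqRecord(taxon, "".join(seq), "dna")
    return records, truth


def recoverable_within_window(truth: list[PlantedSite], motif: str, window: int) -> bool:
    """True if all planted instances of ``motif`` fall within ``window`` bp of
    the first taxon's offset (i.e. the positional-conservation filter can keep
    them)."""
    offsets = [t.offset_from_tis for t in truth if t.motif == motif]
    return all(abs(o - offsets[0]) <= window for o in offsets)


# ---------------------------------------------------------------------------
# Canonical globin fixture


@dataclass(frozen=True)
class HelixAnnotation:
    """Ordered globin helix segments (label, first residue, last residue;
    1-based closed). Residues between annotated helices belong to the linker
    named after the flanking helices (e.g. "CD"); residues before helix A are
    "NA" and after helix H are "HC", following globin nomenclature."""

    segments: tuple[tuple[str, int, int], ...]
    protein_length: int

    def __post_init__(self):
        prev_end = 0
        for label, start, end in self.segments:
            if start > end:
                raise ValueError(f"segment {label}: start > end")
            if start <= prev_end:
                raise ValueError(f"segment {label}: overlaps or out of order")
            prev_end = end
        if prev_end > self.protein_length:
            raise ValueError("segments extend beyond protein length")

    def segment_of(self, residue: int) -> tuple[str, int]:
        """(segment label, 1-based codon index within segment) for a residue."""
        if not (1 <= residue <= self.protein_length):
            raise ValueError(f"residue {residue} outside protein [1, {self.protein_length}]")
        segs = self.segments
        if residue < segs[0][1]:
            return "N" + segs[0][0], residue
        for i, (label, start, end) in enumerate(segs):
            if start <= residue <= end:
                return label, residue - start + 1
            if i + 1 < len(segs) and end < residue < segs[i + 1][1]:
                linker = label + segs[i + 1][0]
                return linker, residue - end
        return segs[-1][0] + "C", residue - segs[-1][2]

    def residue_of(self, segment: str, codon_index: int) -> int:
        """Inverse of :meth:`segment_of`."""
        segs = self.segments
        labels = {label: (start, end) for label, start, end in segs}
        if segment in labels:
            start, end = labels[segment]
            res = start + codon_index - 1
            if res > end:
                raise ValueError(f"codon index {codon_index} beyond segment {segment}")
            return res
        if segment == "N" + segs[0][0]:
            return codon_index
        if segment == segs[-1][0] + "C":
            return segs[-1][2] + codon_index
        for (l1, _s1, e1), (l2, s2, _e2) in zip(segs, segs[1:]):
            if segment == l1 + l2:
                res = e1 + codon_index
                if res >= s2:
                    raise ValueError(f"codon index {codon_index} beyond linker {segment}")
                return res
        raise ValueError(f"unknown segment label {segment!r}")


_FIXTURE_SEED = 42_1988  # frozen; never derived from run seeds
_FIXTURE_CODONS = 150
_FIXTURE_UPSTREAM = 1200  # scaffold bp 5' of the TSS
_FIXTURE_UTR5 = 355
_FIXTURE_DOWNSTREAM = 200
_FIXTURE_INTRON_LEN = 90

CANONICAL_HELICES = HelixAnnotation(
    segments=(
        ("A", 4, 18), ("B", 21, 36), ("C", 37, 43), ("D", 52, 58),
        ("E", 59, 77), ("F", 84, 93), ("G", 101, 118), ("H", 125, 145),
    ),
    protein_length=_FIXTURE_CODONS,
)


@dataclass(frozen=True)
class GlobinTemplate:
    """Frozen 150-codon globin gene template on a synthetic scaffold.

    ``with_introns`` realizes the gene with introns inserted immediately after
    the given CDS nucleotide offsets; ``place_intron`` is the single-intron
    convenience hook.
    """

    cds: str
    utr5: str
    upstream: str
    downstream: str

    @property
    def cds_length(self) -> int:
        return len(self.cds)

    def with_introns(self, after_cds_nt: list[int]) -> tuple[SeqRecord, GeneModel]:
        offsets = sorted(after_cds_nt)
        for n in offsets:
            if not (1 <= n <= len(self.cds) - 1):
                raise ValueError(
                    f"intron position {n} outside [1, {len(self.cds) - 1}]"
                )
        if len(set(offsets)) != len(offsets):
            raise ValueError("duplicate intron positions")
        rng = np.random.default_rng(_FIXTURE_SEED + 1)
        pieces, cds_ivs = [], []
        cursor = len(self.upstream) + len(self.utr5)
        scaffold_parts = [self.upstream, self.utr5]
        prev = 0
        for n in offsets + [len(self.cds)]:
            exon = self.cds[prev:n]
            scaffold_parts.append(exon)
            cds_ivs.append((cursor, cursor + len(exon)))
            cursor += len(exon)
            if n != len(self.cds):
                core = "".join(
                    BASES[i]
                    for i in rng.integers(0, 4, size=_FIXTURE_INTRON_LEN - 4)
                )
                intron = "GT" + core + "AG"
                scaffold_parts.append(intron)
                cursor += len(intron)
            prev = n
        scaffold_parts.append(self.downstream)
        seq = "".join(scaffold_parts)
        tss = len(self.upstream)
        tis = len(self.upstream) + len(self.utr5)
        # first exon carries the 5'UTR; later coding exons coincide with CDS
        exons = [(tss, cds_ivs[0][1])] + [iv for iv in cds_ivs[1:]]
        model = GeneModel(
            gene_id="globin_fixture",
            scaffold="fixture_scaf",
            strand="+",
            exons=exons,
            cds=cds_ivs,
            tss=tss,
            tis=tis,
        )
        return SeqRecord("fixture_scaf", seq, "dna"), model

    def place_intron(self, after_cds_nt: int) -> tuple[SeqRecord, GeneModel]:
        return self.with_introns([after_cds_nt])


def canonical_globin_fixture() -> tuple[GlobinTemplate, HelixAnnotation]:
    """The frozen 150-codon globin gene and its helix annotation.

    Deterministic: the sequence derives from a frozen seed, so two calls
    return byte-identical sequences.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    body = "".join(
        SENSE_CODONS[i]
        for i in rng.integers(0, len(SENSE_CODONS), size=_FIXTURE_CODONS - 1)
    )
    cds = "ATG" + body
    utr5 = "".join(BASES[i] for i in rng.integers(0, 4, size=_FIXTURE_UTR5))
    upstream = "".join(BASES[i] for i in rng.integers(0, 4, size=_FIXTURE_UPSTREAM))
    downstream = "".join(BASES[i] for i in rng.integers(0, 4, size=_FIXTURE_DOWNSTREAM))
    return GlobinTemplate(cds, utr5, upstream, downstream), CANONICAL_HELICES


# ---------------------------------------------------------------------------
# Synthetic loci with anchor-gene neighbourhoods


@dataclass(frozen=True)
class LocusConfig:
    """A multi-species locus: ordered anchor genes with a globin inserted at
    ``globin_position``, introns realized at the given helix-coordinate codes,
    and (optionally) species whose neighbourhood is disrupted."""

    species: tuple[str, ...]
    anchor_genes: tuple[str, ...] = ("POMT2L", "TMEM63CL")
    globin_position: int = 1
    intron_codes: tuple[str, ...] = ("B12.2", "E11.0", "G7.0")
    scramble_species: frozenset = frozenset()
    anchor_codons: int = 100
    spacing_bp: int = 400
    divergence: float = 0.05
    utr5_bp: int = 355

    def __post_init__(self):
        if not (0 <= self.globin_position <= len(self.anchor_genes)):
            raise ValueError("globin_position outside neighbourhood")
        unknown = set(self.scramble_species) - set(self.species)
        if unknown:
            raise ValueError(f"scramble_species not in species list: {sorted(unknown)}")


def build_synthetic_locus(
    config: LocusConfig, seed: int = 0
) -> dict[str, tuple[SeqRecord, list[GeneModel]]]:
    """Per-species scaffolds carrying the configured gene neighbourhood.

    Anchor CDSs and the globin CDS are evolved from common roots along a star
    of branches of length ``divergence`` so that reciprocal-best-hit mapping
    recognises the orthologs. Scrambled species keep the genes but the
    neighbourhood order is permuted and unrelated filler genes are inserted
    next to the globin, breaking adjacency (with three genes alone every
    permutation would leave the globin adjacent to an anchor).
    """
    from .gene_structure import intron_code_to_cds_offset

    rng = np.random.default_rng(seed)
    template, helices = canonical_globin_fixture()
    intron_offsets = [
        intron_code_to_cds_offset(code, helices) for code in config.intron_codes
    ]

    # Root CDS per gene family, then one evolved copy per species.
    star = make_species_tree(max(len(config.species), 2), config.divergence,
                             seed=int(rng.integers(2**31)))
    # overwrite taxa with actual species names (same topology/lengths)
    name_map = dict(zip([lf.taxon.label for lf in star.leaf_node_iter()], config.species))
    for lf in star.leaf_node_iter():
        lf.taxon.label = name_map.get(lf.taxon.label, lf.taxon.label)

    families: dict[str, dict[str, str]] = {}
    for gene in config.anchor_genes:
        root = random_cds(config.anchor_codons, seed=int(rng.integers(2**31)))
        leaves, _ = simulate_codon_evolution(
            root, star,
            CodonEvolutionConfig(omega=0.1, kappa=2.0,
                                 length_codons=config.anchor_codons,
                                 seed=int(rng.integers(2**31))),
        )
        families[gene] = leaves
    globin_leaves, _ = simulate_codon_evolution(
        template.cds, star,
        CodonEvolutionConfig(omega=0.1, kappa=2.0,
                             length_codons=_FIXTURE_CODONS,
                             seed=int(rng.integers(2**31))),
    )

    out: dict[str, tuple[SeqRecord, list[GeneModel]]] = {}
    for sp in config.species:
        order = list(config.anchor_genes)
        order.insert(config.globin_position, "globin")
        scrambled = sp in config.scramble_species
        if scrambled:
            perm = rng.permutation(len(order))
            order = [order[i] for i in perm]
            gi = order.index("globin")
            order[gi:gi] = ["filler1"]
            order.insert(gi + 2, "filler2")
        seq_parts: list[str] = []
        models: list[GeneModel] = []
        cursor = 0
        scaf_name = f"{sp}_scaf1"
        for idx, gene in enumerate(order):
            gap = "".join(BASES[i] for i in rng.integers(0, 4, size=config.spacing_bp))
            seq_parts.append(gap)
            cursor += len(gap)
            strand = "-" if idx % 2 == 1 else "+"
            if gene == "globin":
                piece, model = _globin_gene_piece(
                    sp, scaf_name, cursor, strand, globin_leaves[sp],
                    intron_offsets, config.utr5_bp, rng,
                )
            elif gene.startswith("filler"):
                cds = random_cds(60, seed=int(rng.integers(2**31)))
                piece, model = _simple_gene_piece(
                    f"{sp}_{gene}", scaf_name, cursor, strand, cds
                )
            else:
                piece, model = _simple_gene_piece(
                    f"{sp}_{gene}", scaf_name, cursor, strand, families[gene][sp]
                )
            seq_parts.append(piece)
            cursor += len(piece)
            models.append(model)
        tail = "".join(BASES[i] for i in rng.integers(0, 4, size=config.spacing_bp))
        seq_parts.append(tail)
        out[sp] = (SeqRecord(scaf_name, "".join(seq_parts), "dna"), models)
    return out


def _simple_gene_piece(
    gene_id: str, scaffold: str, start: int, strand: str, cds: str
) -> tuple[str, GeneModel]:
    seq = cds if strand == "+" else revcomp(cds)
    iv = (start, start + len(cds))
    tss = iv[0] if strand == "+" else iv[1] - 1
    model = GeneModel(gene_id, scaffold, strand, [iv], [iv], tss, tss)
    return seq, model


def _globin_gene_piece(
    sp: str, scaffold: str, start: int, strand: str, cds: str,
    intron_offsets: list[int], utr5_bp: int, rng: np.random.Generator,
) -> tuple[str, GeneModel]:
    offsets = sorted(intron_offsets)
    utr = "".join(BASES[i] for i in rng.integers(0, 4, size=utr5_bp))
    parts, cds_ivs = [utr], []
    cursor = start + len(utr)
    prev = 0
    for n in offsets + [len(cds)]:
        exon = cds[prev:n]
        parts.append(exon)
        cds_ivs.append((cursor, cursor + len(exon)))
        cursor += len(exon)
        if n != len(cds):
            core = "".join(BASES[i] for i in rng.integers(0, 4, size=_FIXTURE_INTRON_LEN - 4))
            parts.append("GT" + core + "AG")
            cursor += _FIXTURE_INTRON_LEN
        prev = n
    plus_seq = "".join(parts)
    tss_plus = start
    tis_plus = start + len(utr)
    exons_plus = [(tss_plus, cds_ivs[0][1])] + [iv for iv in cds_ivs[1:]]
    if strand == "+":
        model = GeneModel(f"{sp}_globin", scaffold, "+", exons_plus, cds_ivs,
                          tss_plus, tis_plus)
        return plus_seq, model
    # minus strand: reverse-complement the piece and mirror coordinates
    end = start + len(plus_seq)

    def mirror(iv: tuple[int, int]) -> tuple[int, int]:
        # interval [a,b) within [start,end) mapped onto the revcomp'd piece
        a, b = iv
        return (start + (end - b), start + (end - a))

    exons_m = [mirror(iv) for iv in exons_plus]
    cds_m = [mirror(iv) for iv in cds_ivs]
    tss_m = start + (end - 1 - tss_plus)
    tis_m = start + (end - 1 - tis_plus)
    model = GeneModel(f"{sp}_globin", scaffold, "-", exons_m, cds_m, tss_m, tis_m)
    return revcomp(plus_seq), model
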