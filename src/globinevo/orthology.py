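"""Ortholog candidates by reciprocal best hits and shared-synteny testing.

Candidate orthologs are detected exactly as in classical proteome
comparisons: each protein is aligned against every protein of the other
proteome with a Smith–Waterman local alignment under BLOSUM45 with affine
gap costs (open 11, extend 1), and a pair is reported when each member is
the other's unique best hit. At desk scale the exact aligner replaces the
heuristic BLAST search, and a raw-score floor replaces the E-value threshold
(no database size exists here to calibrate E-values against).

Shared synteny — adjacency of the focal (globin) gene to an RBH-mapped
anchor gene (POMT2/TMEM63C analogues) on the same scaffold — is the
strongest orthology evidence the pipeline produces; adjacency means zero
intervening annotated genes and is orientation-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import GeneModel, SeqRecord

DEFAULT_MIN_SCORE = 50.0


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM45"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class Hit:
    query: str
    subject: str
    score: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]


@dataclass(frozen=True)
class RBHPair:
    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.matrix)
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=matrix,
        open_gap_score=-params.gap_open,
        extend_gap_score=-params.gap_extend,
    )
    return aligner


def local_align(a: SeqRecord, b: SeqRecord, params: AlignParams = AlignParams()) -> Hit:
    """Optimal Smith–Waterman local alignment score and one optimal alignment.

    A gap of length k costs gap_open + (k-1) * gap_extend. An all-negative
    comparison yields score 0 with empty intervals (the local-alignment floor).
    """
    matrix = substitution_matrices.load(params.matrix)
    alphabet = set(str(matrix.alphabet))
    for rec in (a, b):
        bad = set(rec.seq) - alphabet
        if bad:
            raise ValueError(
                f"residue {sorted(bad)[0]!r} in {rec.id!r} absent from {params.matrix}"
            )
    aligner = _aligner(params)
    score = float(aligner.score(a.seq, b.seq))
    if score <= 0:
        return Hit(a.id, b.id, 0.0, (0, 0), (0, 0))
    aln = next(iter(aligner.align(a.seq, b.seq)))
    qa = aln.aligned[0]
    sa = aln.aligned[1]
    q_iv = (int(qa[0][0]), int(qa[-1][1])) if len(qa) else (0, 0)
    s_iv = (int(sa[0][0]), int(sa[-1][1])) if len(sa) else (0, 0)
    return Hit(a.id, b.id, score, q_iv, s_iv)


def _best_hits(
    queries: list[SeqRecord], subjects: list[SeqRecord], params: AlignParams
) -> dict[str, tuple[str, float]]:
    """Best subject per query; score ties broken by smallest subject id."""
    aligner = _aligner(params)
    best: dict[str, tuple[str, float]] = {}
    for q in queries:
        top: tuple[float, str] | None = None
        for s in subjects:
            score = float(aligner.score(q.seq, s.seq))
            cand = (-score, s.id)
            if top is None or cand < top:
                top = cand
        if top is not None:
            best[q.id] = (top[1], -top[0])
    return best


def reciprocal_best_hits(
    proteome_a: list[SeqRecord],
    proteome_b: list[SeqRecord],
    params: AlignParams = AlignParams(),
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[RBHPair]:
    """Pairs (x, y) where y is x's best hit in B and x is y's best hit in A,
    both scores >= min_score, after deterministic tie-breaking."""
    if not proteome_a or not proteome_b:
        return []
    ab = _best_hits(proteome_a, proteome_b, params)
    ba = _best_hits(proteome_b, proteome_a, params)
    pairs = []
    for x, (y, s_ab) in sorted(ab.items()):
        back = ba.get(y)
        if back is None:
            continue
        if back[0] == x and s_ab >= min_score and back[1] >= min_score:
            pairs.append(RBHPair(x, y, s_ab, back[1]))
    return pairs


# ---------------------------------------------------------------------------
# Shared synteny


@dataclass
class SpeciesSyntenyStatus:
    species: str
    status: str  # "adjacent" | "same_scaffold" | "no_shared_scaffold" | "not_found"
    nearest_anchor: str | None = None
    intervening_genes: int | None = None
    strand: str | None = None


@dataclass
class SyntenyPairReport:
    species_a: str
    species_b: str
    anchor_matches: list[tuple[str, str]]
    status_a: SpeciesSyntenyStatus | None
    status_b: SpeciesSyntenyStatus | None

    @property
    def shared_synteny(self) -> bool:
        return bool(
            self.status_a and self.status_b
            and self.status_a.status == "adjacent"
            and self.status_b.status == "adjacent"
        )


@dataclass
class SyntenyReport:
    pairs: list[SyntenyPairReport] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["species_a\tspecies_b\tanchor_matches\tstatus_a\tstatus_b\t"
                 "intervening_a\tintervening_b\tshared_synteny"]
        for p in self.pairs:
            anchors = ",".join(f"{a}:{b}" for a, b in p.anchor_matches) or "."
            sa = p.status_a.status if p.status_a else "not_found"
            sb = p.status_b.status if p.status_b else "not_found"
            ia = p.status_a.intervening_genes if p.status_a else None
            ib = p.status_b.intervening_genes if p.status_b else None
            lines.append(
                f"{p.species_a}\t{p.species_b}\t{anchors}\t{sa}\t{sb}\t"
                f"{'.' if ia is None else ia}\t{'.' if ib is None else ib}\t"
                f"{'yes' if p.shared_synteny else 'no'}"
            )
        return "\n".join(lines) + "\n"


def _focal_status(
    models: list[GeneModel], focal_gene_name: str, anchor_ids: set[str]
) -> SpeciesSyntenyStatus | None:
    focal = [m for m in models if focal_gene_name in m.gene_id]
    if not focal:
        return None
    focal_model = focal[0]
    same_scaf = sorted(
        (m for m in models if m.scaffold == focal_model.scaffold),
        key=lambda m: m.span()[0],
    )
    idx = same_scaf.index(focal_model)
    anchors_here = [
        (i, m) for i, m in enumerate(same_scaf) if m.gene_id in anchor_ids
    ]
    if not anchors_here:
        return SpeciesSyntenyStatus(
            species="", status="no_shared_scaffold", strand=focal_model.strand
        )
    nearest_i, nearest = min(anchors_here, key=lambda im: abs(im[0] - idx))
    gap = abs(nearest_i - idx) - 1
    status = "adjacent" if gap == 0 else "same_scaffold"
    return SpeciesSyntenyStatus(
        species="", status=status, nearest_anchor=nearest.gene_id,
        intervening_genes=gap, strand=focal_model.strand,
    )


def shared_synteny(
    models_by_species: dict[str, list[GeneModel]],
    rbh_map: dict[tuple[str, str], list[RBHPair] | list[tuple[str, str]]],
    anchors: list[str],
    focal_gene_name: str = "globin",
) -> SyntenyReport:
    """Per species-pair shared-synteny report for the focal gene.

    ``rbh_map`` gives, per (species_a, species_b) key, the RBH gene-id pairs
    linking their proteomes; an anchor counts as matched when an RBH pair
    joins genes whose ids carry the anchor name in both species. Adjacency is
    evaluated against RBH-matched anchors only, in each species separately.
    """
    species = list(models_by_species)
    report = SyntenyReport()
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1 :]:
            pairs = rbh_map.get((sp_a, sp_b)) or rbh_map.get((sp_b, sp_a)) or []
            norm = [
                (p.gene_a, p.gene_b) if isinstance(p, RBHPair) else tuple(p)
                for p in pairs
            ]
            anchor_matches = []
            matched_a: set[str] = set()
            matched_b: set[str] = set()
            for anchor in anchors:
                for ga, gb in norm:
                    if anchor in ga and anchor in gb:
                        anchor_matches.append((ga, gb))
                        matched_a.add(ga)
                        matched_b.add(gb)
                        break
            sa = _focal_status(models_by_species[sp_a], focal_gene_name, matched_a)
            sb = _focal_status(models_by_species[sp_b], focal_gene_name, matched_b)
            if sa:
                sa.species = sp_a
            if sb:
                sb.species = sp_b
            report.pairs.append(
                SyntenyPairReport(sp_a, sp_b, anchor_matches, sa, sb)
            )
    return report
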