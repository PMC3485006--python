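"""Phylogenetic footprinting: promoter extraction, PWM scanning, positional
conservation, substring-parsimony motif discovery, and consensus scanning.

The promoter region is 1000 bp upstream of the TSS plus the full 5'UTR plus
the first 20 bp of the CDS, addressed in TIS-relative coordinates (−1 is the
base immediately upstream of the ATG, +1 the A of the ATG; there is no 0).
PWM hits are thresholded on a min–max relative score so that "75–85%"
thresholds are reproducible without any proprietary score profiles; a site is
positionally conserved when every species contributes a hit within a 50-bp
window of the reference species' offset. Motif discovery minimises the number
of substitutions needed to explain one k-mer occurrence per species on the
phylogeny (substring parsimony, k = 8, total mutations ≤ 3, ≤ 1 per branch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np

from .pwm import BASES, PWM
from .seqio import GeneModel, SeqRecord, revcomp
from .synthetic import IUPAC_DNA
from .trees import node_name

logger = logging.getLogger("globinevo")

BASE_TO_I = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# Promoter regions


@dataclass
class PromoterRegion:
    """A promoter sequence with a TIS-anchored coordinate map.

    ``tis_index`` is the string index of the A of the start codon; TIS-relative
    offsets skip 0 (−1 is immediately upstream of +1).
    """

    taxon: str
    seq: str
    tis_index: int
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def offset_at(self, index: int) -> int:
        return index - self.tis_index + 1 if index >= self.tis_index else index - self.tis_index

    def index_of(self, offset: int) -> int:
        if offset == 0:
            raise ValueError("TIS-relative coordinates have no position 0")
        return self.tis_index + offset - 1 if offset > 0 else self.tis_index + offset


def extract_promoter_region(
    gene: GeneModel,
    scaffold: SeqRecord,
    upstream: int = 1000,
    cds_inset: int = 20,
) -> PromoterRegion:
    """Strand-aware extraction of the promoter region, 5'→3'.

    Region = ``upstream`` bp before the TSS + 5'UTR + first ``cds_inset`` bp
    of the CDS (length 1020 + UTR for the defaults). Scaffolds too short
    upstream truncate the region with a warning.
    """
    seq = scaffold.seq
    if gene.strand == "+":
        want_start = gene.tss - upstream
        start = max(0, want_start)
        end = min(len(seq), gene.tis + cds_inset)
        piece = seq[start:end]
        tis_index = gene.tis - start
        truncated = start != want_start or end != gene.tis + cds_inset
    else:
        want_end = gene.tss + upstream + 1
        end = min(len(seq), want_end)
        start = max(0, gene.tis - cds_inset + 1)
        piece = revcomp(seq[start:end])
        tis_index = (end - 1) - gene.tis
        truncated = end != want_end or start != gene.tis - cds_inset + 1
    if truncated:
        logger.warning(
            "%s: promoter region truncated to %d bp by scaffold edge",
            gene.gene_id, len(piece),
        )
    return PromoterRegion(gene.gene_id, piece, tis_index, truncated)


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass(frozen=True)
class PWMHit:
    taxon: str
    pwm_name: str
    offset: int  # TIS-relative offset of the hit's 5'-most region position
    strand: str
    score: float
    rel_score: float


def scan_pwm(
    region: PromoterRegion, pwm: PWM, rel_threshold: float = 0.8
) -> list[PWMHit]:
    """Scan both strands; windows containing ambiguous bases are skipped.

    Relative score = (raw − min_possible) / (max_possible − min_possible)
    over the log-odds matrix; hits with relative score >= threshold are
    returned sorted by offset.
    """
    if not (0 <= rel_threshold <= 1):
        raise ValueError("rel_threshold must be in [0, 1]")
    w = pwm.width
    seq = region.seq.upper()
    if len(seq) < w:
        return []
    lo = pwm.log_odds
    lo_rc = pwm.reverse_complement().log_odds
    span = pwm.max_score - pwm.min_score
    codes = np.array([BASE_TO_I.get(ch, -1) for ch in seq])
    hits = []
    for i in range(len(seq) - w + 1):
        window = codes[i : i + w]
        if np.any(window < 0):
            continue
        cols = np.arange(w)
        for strand, mat in (("+", lo), ("-", lo_rc)):
            raw = float(mat[window, cols].sum())
            rel = (raw - pwm.min_score) / span if span > 0 else 1.0
            if rel >= rel_threshold:
                hits.append(
                    PWMHit(region.taxon, pwm.name, region.offset_at(i), strand,
                           raw, rel)
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def pair_hits_by_flank_identity(
    hit_a: PWMHit,
    hit_b: PWMHit,
    regions: dict[str, PromoterRegion],
    pwm_width: int,
    flank: int = 5,
    identity_threshold: float = 0.5,
) -> bool:
    """True iff ungapped identity over the concatenated ``flank``-bp left and
    right flanks of the two hits reaches the threshold.

    Flanks truncated by region edges shrink the denominator accordingly.
    """
    if hit_a.pwm_name != hit_b.pwm_name:
        raise ValueError("hits are for different PWMs")
    if not (0 <= identity_threshold <= 1):
        raise ValueError("identity_threshold must be in [0, 1]")

    def flanks(hit: PWMHit) -> tuple[str, str]:
        region = regions[hit.taxon]
        i = region.index_of(hit.offset)
        left = region.seq[max(0, i - flank) : i]
        right = region.seq[i + pwm_width : i + pwm_width + flank]
        return left, right

    la, ra = flanks(hit_a)
    lb, rb = flanks(hit_b)
    matches = compared = 0
    # left flanks align right-justified (adjacent to the hit)
    for x, y in zip(reversed(la), reversed(lb)):
        compared += 1
        matches += x == y
    for x, y in zip(ra, rb):
        compared += 1
        matches += x == y
    if compared == 0:
        return False
    return matches / compared >= identity_threshold


# ---------------------------------------------------------------------------
# Positional conservation (the 50-bp rule)


@dataclass(frozen=True)
class ConservedSite:
    pwm_name: str
    offsets: tuple[tuple[str, int], ...]  # (taxon, TIS-relative offset)
    max_deviation: int


def positional_conservation_filter(
    hits_by_taxon: dict[str, list[PWMHit]],
    window: int = 50,
    require_flank_pairing: bool = False,
    regions: dict[str, PromoterRegion] | None = None,
    pwm_widths: dict[str, int] | None = None,
    flank: int = 5,
    identity_threshold: float = 0.5,
) -> list[ConservedSite]:
    """TFBSs positionally conserved among all taxa within ``window`` bp.

    The first taxon in configuration order is the reference; for each of its
    hits, every other taxon must contribute a hit for the same PWM within
    ``window`` bp of the reference offset (closest such hit selected).
    Optional flank pairing is applied between the reference hit and each
    selected hit.
    """
    taxa = list(hits_by_taxon)
    if not taxa:
        return []
    reference = taxa[0]
    others = taxa[1:]
    sites = []
    seen = set()
    for ref_hit in hits_by_taxon[reference]:
        chosen = [(reference, ref_hit.offset)]
        ok = True
        for taxon in others:
            candidates = [
                h for h in hits_by_taxon[taxon]
                if h.pwm_name == ref_hit.pwm_name
                and abs(h.offset - ref_hit.offset) <= window
            ]
            if require_flank_pairing and regions is not None:
                width = (pwm_widths or {}).get(ref_hit.pwm_name, 0)
                candidates = [
                    h for h in candidates
                    if pair_hits_by_flank_identity(
                        ref_hit, h, regions, width, flank, identity_threshold
                    )
                ]
            if not candidates:
                ok = False
                break
            pick = min(candidates, key=lambda h: (abs(h.offset - ref_hit.offset), h.offset))
            chosen.append((taxon, pick.offset))
        if not ok:
            continue
        deviation = max(abs(off - ref_hit.offset) for _, off in chosen)
        site = ConservedSite(ref_hit.pwm_name, tuple(chosen), deviation)
        key = (site.pwm_name, site.offsets)
        if key not in seen:
            seen.add(key)
            sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# Substring parsimony (FootPrinter-style motif discovery)


@dataclass(frozen=True)
class ParsimonyMotif:
    width: int
    consensus: str  # root label
    instances: tuple[tuple[str, int, str], ...]  # (taxon, position, substring)
    score: int
    branch_counts: tuple[tuple[str, int], ...]  # (child node name, mutations)


@lru_cache(maxsize=8)
def _neighbor_table(k: int) -> np.ndarray:
    """(4**k, 3k) table of all Hamming-1 neighbours of each k-mer code."""
    n = 4**k
    codes = np.arange(n)
    cols = []
    for pos in range(k):
        shift = 4**pos
        digit = (codes // shift) % 4
        for delta in range(1, 4):
            cols.append(codes + ((digit + delta) % 4 - digit) * shift)
    return np.stack(cols, axis=1)


def _relax(cost: np.ndarray, table: np.ndarray, cap: int) -> np.ndarray:
    """One unit-mutation relaxation: min(cost[w], 1 + min over neighbours)."""
    neigh = cost[table].min(axis=1) + 1
    return np.minimum(cost, np.minimum(neigh, cap))


def _kmer_code(kmer: str) -> int:
    code = 0
    for i, ch in enumerate(kmer):
        code += BASE_TO_I[ch] * 4**i
    return code


def _code_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(out)


def _hamming_codes(a: int, b: int, k: int) -> int:
    h = 0
    for _ in range(k):
        h += (a % 4) != (b % 4)
        a //= 4
        b //= 4
    return h


def substring_parsimony_search(
    regions_by_taxon: dict[str, "str | SeqRecord | PromoterRegion"],
    tree: dendropy.Tree,
    k: int = 8,
    max_total: int = 3,
    max_per_branch: int = 1,
) -> list[ParsimonyMotif]:
    """All motifs of width ``k`` explainable with ≤ ``max_total`` substitutions
    on the tree, at most ``max_per_branch`` per branch, one occurrence per
    taxon, positions unconstrained across taxa.

    Bottom-up Sankoff over all 4**k ancestral labels with unit substitution
    costs (branch transitions limited to ``max_per_branch`` changes), then a
    deterministic traceback per qualifying root label; motifs with identical
    per-taxon instances are deduplicated.
    """
    cap = max_total + 1  # sentinel: "worse than any reportable motif"
    table = _neighbor_table(k)
    n_states = 4**k

    seqs: dict[str, str] = {}
    for taxon, region in regions_by_taxon.items():
        seq = region if isinstance(region, str) else region.seq
        seq = seq.upper()
        if len(seq) < k:
            logger.warning("region for %s shorter than k=%d; excluded", taxon, k)
            continue
        seqs[taxon] = seq

    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    use = leaves & set(seqs)
    if leaves - set(seqs):
        tree = tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(use))
    from .trees import label_internal_nodes
    label_internal_nodes(tree)

    # occurrence positions per leaf, per k-mer code
    occ: dict[str, dict[int, int]] = {}
    for taxon in use:
        seq = seqs[taxon]
        first: dict[int, int] = {}
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(ch not in BASE_TO_I for ch in window):
                continue
            code = _kmer_code(window)
            if code not in first:
                first[code] = i
        occ[taxon] = first

    # Sankoff bottom-up: cost_sub[node][w] = min mutations in the subtree
    # given the node is labelled w (branch above the node not included).
    cost_above: dict[int, np.ndarray] = {}  # includes the branch to the parent
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            own = np.full(n_states, cap, dtype=np.int32)
            codes = list(occ[node.taxon.label])
            own[codes] = 0
        else:
            own = np.zeros(n_states, dtype=np.int32)
            for child in node.child_nodes():
                own = np.minimum(own + cost_above[id(child)], cap)
        if node is not tree.seed_node:
            trans = own.copy()
            for _ in range(max_per_branch):
                trans = _relax(trans, table, cap)
            cost_above[id(node)] = trans
        else:
            root_cost = own

    qualifying = np.flatnonzero(root_cost <= max_total).tolist()
    # ascending parsimony score so dedup keeps the best label per instance set
    qualifying.sort(key=lambda c: (int(root_cost[c]), c))
    motifs: list[ParsimonyMotif] = []
    seen_instances = set()
    for root_code in qualifying:
        instances: list[tuple[str, int, str]] = []
        branch_counts: list[tuple[str, int]] = []
        total = 0

        def descend(node, label):
            nonlocal total
            for child in node.child_nodes():
                if child.is_leaf():
                    # best occurrence within max_per_branch of the label
                    best = None
                    for code2 in occ[child.taxon.label]:
                        h = _hamming_codes(label, code2, k)
                        if h <= max_per_branch:
                            cand = (h, occ[child.taxon.label][code2], code2)
                            if best is None or cand < best:
                                best = cand
                    h, pos, code2 = best
                    instances.append((child.taxon.label, pos, _code_kmer(code2, k)))
                    branch_counts.append((node_name(child) or child.taxon.label, h))
                    total += h
                else:
                    own_child = np.zeros(n_states, dtype=np.int64)
                    for gc in child.child_nodes():
                        own_child = own_child + cost_above[id(gc)]
                    # candidates: label itself and everything within
                    # max_per_branch mutations of it
                    cand_codes = {label}
                    frontier = {label}
                    for _ in range(max_per_branch):
                        nxt = set()
                        for c in frontier:
                            nxt.update(int(x) for x in table[c])
                        cand_codes |= nxt
                        frontier = nxt
                    best = None
                    for c in sorted(cand_codes):
                        h = _hamming_codes(label, c, k)
                        if h > max_per_branch:
                            continue
                        val = (int(own_child[c]) + h, h, c)
                        if best is None or val < best:
                            best = val
                    _, h, chosen = best
                    branch_counts.append((node_name(child) or "", h))
                    total += h
                    descend(child, chosen)

        descend(tree.seed_node, root_code)
        key = tuple(sorted(instances))
        if key in seen_instances:
            continue
        if total > max_total:
            continue
        seen_instances.add(key)
        motifs.append(
            ParsimonyMotif(
                width=k,
                consensus=_code_kmer(root_code, k),
                instances=tuple(sorted(instances)),
                score=total,
                branch_counts=tuple(branch_counts),
            )
        )
    motifs.sort(key=lambda m: (m.score, m.instances))
    return motifs


# ---------------------------------------------------------------------------
# IUPAC consensus scanning (NRSE search)


@dataclass(frozen=True)
class ConsensusPattern:
    name: str
    iupac: str
    max_mismatches: int = 0

    def __post_init__(self):
        bad = set(self.iupac.upper()) - set(IUPAC_DNA)
        if bad:
            raise ValueError(f"pattern {self.name}: invalid IUPAC symbol {sorted(bad)[0]!r}")


@dataclass(frozen=True)
class ConsensusHit:
    pattern: str
    offset: int  # relative to the gene's TSS, transcript orientation
    strand: str
    mismatches: int


def iupac_scan(seq: str, pattern: ConsensusPattern) -> list[tuple[int, str, int]]:
    """(position, strand, mismatches) for matches on both strands of ``seq``."""
    pat = pattern.iupac.upper()
    sets = [IUPAC_DNA[s] for s in pat]
    L = len(pat)
    seq = seq.upper()
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(len(s) - L + 1):
            mm = 0
            for j in range(L):
                if s[i + j] not in sets[j]:
                    mm += 1
                    if mm > pattern.max_mismatches:
                        break
            else:
                pos = i if strand == "+" else len(s) - i - L
                out.append((pos, strand, mm))
    out.sort()
    return out


def scan_consensus_patterns(
    scaffold: SeqRecord,
    gene: GeneModel,
    patterns: list[ConsensusPattern],
    span: int = 5000,
) -> list[ConsensusHit]:
    """Scan ``span`` bp either side of the gene for consensus patterns.

    Offsets are reported relative to the TSS in transcript orientation
    (negative = upstream of the gene). The window is truncated at scaffold
    edges with a warning.
    """
    g_start, g_end = gene.span()
    want_start, want_end = g_start - span, g_end + span
    start = max(0, want_start)
    end = min(len(scaffold.seq), want_end)
    if (start, end) != (want_start, want_end):
        logger.warning(
            "%s: ±%d bp window truncated to scaffold [%d, %d)",
            gene.gene_id, span, start, end,
        )
    window = scaffold.seq[start:end]
    hits = []
    for pattern in patterns:
        for pos, strand, mm in iupac_scan(window, pattern):
            scaf_pos = start + pos  # 5'-most scaffold coordinate of the match
            if gene.strand == "+":
                offset = scaf_pos - gene.tss
                rel_strand = strand
            else:
                match_end = scaf_pos + len(pattern.iupac) - 1
                offset = gene.tss - match_end
                rel_strand = "+" if strand == "-" else "-"
            hits.append(ConsensusHit(pattern.name, offset, rel_strand, mm))
    hits.sort(key=lambda h: (h.pattern, h.offset, h.strand))
    return hits


def read_consensus_patterns(path) -> list[ConsensusPattern]:
    """Read a pattern file: name <TAB> IUPAC [<TAB> max_mismatches] per line."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            mm = int(parts[2]) if len(parts) > 2 else 0
            out.append(ConsensusPattern(parts[0], parts[1], mm))
    return out


# ---------------------------------------------------------------------------
# Matching discovered motifs against a PWM library


@dataclass(frozen=True)
class LibraryMatch:
    name: str
    similarity: float
    strand: str
    offset: int
    n_columns: int
    uninformative: bool = False


def _column_correlations(a: np.ndarray, b: np.ndarray) -> list[float]:
    """Per-column Pearson correlations between two aligned 4×w blocks,
    skipping columns where either side has zero variance."""
    out = []
    for col in range(a.shape[1]):
        x, y = a[:, col], b[:, col]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out.append(float(np.corrcoef(x, y)[0, 1]))
    return out


def match_motif_library(
    instances: list[str], library: list[PWM], min_overlap: int = 4
) -> list[LibraryMatch]:
    """Rank library PWMs by similarity to the motif defined by ``instances``.

    Instances are stacked into a pseudocounted probability matrix; similarity
    is the maximum over ungapped offsets and both orientations of the mean
    per-column Pearson correlation over >= ``min_overlap`` overlapping
    columns. Degenerate (zero-variance) columns are skipped; a comparison
    with no informative columns is flagged uninformative.
    """
    if not instances:
        raise ValueError("need at least one motif instance")
    if not library:
        raise ValueError("empty PWM library")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise ValueError("motif instances have unequal lengths")
    if width < min_overlap:
        raise ValueError(f"motif of width {width} too short to match")
    counts = np.zeros((4, width))
    for inst in instances:
        for i, ch in enumerate(inst.upper()):
            if ch in BASE_TO_I:
                counts[BASE_TO_I[ch], i] += 1
    motif = PWM.from_counts("query", counts)
    matches = []
    for lib_pwm in library:
        best: tuple[float, str, int, int] | None = None
        any_columns = False
        for strand, probs in (("+", motif.probs), ("-", motif.reverse_complement().probs)):
            for offset in range(-(width - min_overlap), lib_pwm.width - min_overlap + 1):
                a_lo = max(0, -offset)
                b_lo = max(0, offset)
                n = min(width - a_lo, lib_pwm.width - b_lo)
                if n < min_overlap:
                    continue
                cors = _column_correlations(
                    probs[:, a_lo : a_lo + n], lib_pwm.probs[:, b_lo : b_lo + n]
                )
                if not cors:
                    continue
                any_columns = True
                sim = float(np.mean(cors))
                cand = (sim, strand, offset, len(cors))
                if best is None or sim > best[0]:
                    best = cand
        if best is None:
            matches.append(LibraryMatch(lib_pwm.name, float("nan"), "+", 0, 0, True))
        else:
            sim, strand, offset, ncols = best
            matches.append(LibraryMatch(lib_pwm.name, sim, strand, offset, ncols))
    matches.sort(key=lambda m: (-(m.similarity if not m.uninformative else -2), m.name))
    return matches
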