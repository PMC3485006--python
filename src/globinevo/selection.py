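"""Branch-wise selection analysis: parsimony ancestors, Nei–Gojobori Ka/Ks,
and sliding-window missense profiles.

Ancestral CDSs are reconstructed by nucleotide-level Fitch parsimony
(deterministic alphabetical tie-break), and Ka/Ks per branch is computed by
the Nei–Gojobori (1986) counting method with Jukes–Cantor correction:
per-codon synonymous/nonsynonymous site fractions from the nine single-base
mutations (mutations to stop codons excluded from the site denominator),
observed differences averaged over all stop-avoiding mutational pathways.
Ka/Ks < 1 indicates purifying selection; a branch with Ks = 0 and Ka > 0 has
an undefined ratio, which is flagged and never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import log

import dendropy

from .codons import AA_OF, codons_of, is_stop
from .trees import label_internal_nodes, node_name

FITCH_ALPHABET = "ACGT-"  # tie-break order; gap treated as a fifth state
GAP_CODON = "---"


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction


@dataclass
class AncestralReconstruction:
    sequences: dict[str, str]  # node label -> CDS (leaves included)
    ambiguity: dict[str, list[frozenset]]  # internal node label -> per-site sets
    score: int


def fitch_ancestral(
    tree: dendropy.Tree, alignment: dict[str, str]
) -> AncestralReconstruction:
    """Per-site Fitch sets bottom-up, top-down resolution with alphabetical
    tie-break; score is the number of union events summed over sites."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaves != set(alignment):
        only_tree = sorted(leaves - set(alignment))
        only_aln = sorted(set(alignment) - leaves)
        raise ValueError(
            f"tree/alignment taxon mismatch: tree-only {only_tree}, "
            f"alignment-only {only_aln}"
        )
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences have unequal lengths")
    ncols = lengths.pop()
    label_internal_nodes(tree)
    post = list(tree.postorder_node_iter())
    sets: dict[int, list[frozenset]] = {}
    score = 0
    for node in post:
        if node.is_leaf():
            seq = alignment[node.taxon.label].upper()
            sets[id(node)] = [frozenset(ch) for ch in seq]
        else:
            kids = [sets[id(c)] for c in node.child_nodes()]
            merged = []
            for col in range(ncols):
                s = kids[0][col]
                for k in kids[1:]:
                    inter = s & k[col]
                    if inter:
                        s = inter
                    else:
                        s = s | k[col]
                        score += 1
                merged.append(s)
            sets[id(node)] = merged
    # top-down resolution
    state: dict[int, list[str]] = {}
    for node in tree.preorder_node_iter():
        own = sets[id(node)]
        if node is tree.seed_node:
            state[id(node)] = [
                min(s, key=FITCH_ALPHABET.index) for s in own
            ]
        else:
            parent = state[id(node.parent_node)]
            state[id(node)] = [
                parent[col] if parent[col] in own[col]
                else min(own[col], key=FITCH_ALPHABET.index)
                for col in range(ncols)
            ]
    sequences, ambiguity = {}, {}
    for node in tree.preorder_node_iter():
        name = node_name(node)
        sequences[name] = "".join(state[id(node)])
        if not node.is_leaf():
            ambiguity[name] = sets[id(node)]
    return AncestralReconstruction(sequences, ambiguity, score)


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes syn/(3 - stops) synonymously; the two fractions
    sum to 1 per position, so S + N = 3 for every sense codon.
    """
    if is_stop(codon):
        raise ValueError(f"stop codon {codon}")
    syn_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if is_stop(alt):
                continue
            valid += 1
            if AA_OF[alt] == AA_OF[codon]:
                syn += 1
        if valid:
            syn_total += syn / valid
    return syn_total, 3.0 - syn_total


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) observed differences between two sense
    codons, averaged over all stop-avoiding mutational pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_acc, non_acc, n_paths = 0.0, 0.0, 0
    for order in permutations(diff_pos):
        cur = c1
        syn, non = 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_acc += syn
            non_acc += non
            n_paths += 1
    if n_paths == 0:
        # every pathway passes through a stop codon; fall back to allowing
        # them (vanishingly rare between real sense codons)
        for order in permutations(diff_pos):
            cur = c1
            syn, non = 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                syn += AA_OF.get(cur) == AA_OF.get(nxt)
                non += AA_OF.get(cur) != AA_OF.get(nxt)
                cur = nxt
            syn_acc += syn
            non_acc += non
            n_paths += 1
    return syn_acc / n_paths, non_acc / n_paths


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"JC correction undefined for p = {p:.4f} >= 3/4")
    return -0.75 * log(1 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class NG86Result:
    ka: float
    ks: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float


def ng86_pair(cds1: str, cds2: str, skip_stop_codons: bool = False) -> NG86Result:
    """Nei–Gojobori Ka/Ks counting between two aligned CDSs.

    Gap codons (``---`` or any codon containing ``-``) are excluded pairwise;
    site counts are averaged between the two sequences; Jukes–Cantor
    correction is applied to the proportions. With ``skip_stop_codons`` codon
    pairs containing a stop are masked like gaps instead of raising — needed
    when one side is a parsimony-reconstructed ancestor, which the
    nucleotide-level reconstruction does not constrain to be stop-free.
    """
    if len(cds1) != len(cds2):
        raise ValueError("CDS lengths differ")
    pairs = [
        (a, b)
        for a, b in zip(codons_of(cds1.upper()), codons_of(cds2.upper()))
        if "-" not in a and "-" not in b
    ]
    if skip_stop_codons:
        pairs = [(a, b) for a, b in pairs if not (is_stop(a) or is_stop(b))]
    for a, b in pairs:
        if is_stop(a) or is_stop(b):
            raise ValueError(f"internal stop codon in compared codons ({a}, {b})")
    if not pairs:
        return NG86Result(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    s_sites = n_sites = sd = nd = 0.0
    for a, b in pairs:
        s1, n1 = _codon_sites(a)
        s2, n2 = _codon_sites(b)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        ds, dn = _codon_differences(a, b)
        sd += ds
        nd += dn
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    return NG86Result(jukes_cantor(pn), jukes_cantor(ps), n_sites, s_sites, nd, sd)


# ---------------------------------------------------------------------------
# Branch-wise Ka/Ks


@dataclass(frozen=True)
class BranchKaKs:
    parent: str
    child: str
    ka: float
    ks: float
    ratio: float | None
    flag: str  # "ok" | "undefined" | "no_change"


def branch_kaks(
    tree: dendropy.Tree,
    alignment: dict[str, str],
    reconstruction: AncestralReconstruction,
) -> list[BranchKaKs]:
    """NG86 applied to (parent sequence, child sequence) for every branch."""
    seqs = dict(reconstruction.sequences)
    seqs.update(alignment)
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node_name(node.parent_node)
        child = node_name(node)
        res = ng86_pair(seqs[parent], seqs[child], skip_stop_codons=True)
        if res.sd == 0 and res.nd == 0:
            out.append(BranchKaKs(parent, child, 0.0, 0.0, None, "no_change"))
        elif res.ks == 0:
            out.append(BranchKaKs(parent, child, res.ka, 0.0, None, "undefined"))
        else:
            out.append(
                BranchKaKs(parent, child, res.ka, res.ks, res.ka / res.ks, "ok")
            )
    return out


def pooled_kaks(branches: list[BranchKaKs]) -> float | None:
    """Mean of the defined per-branch ratios (None if none are defined)."""
    defined = [b.ratio for b in branches if b.flag == "ok"]
    return sum(defined) / len(defined) if defined else None


# ---------------------------------------------------------------------------
# Sliding-window missense profile


@dataclass(frozen=True)
class Window:
    start: int  # 0-based CDS offset
    end: int
    count: int
    partial: bool


@dataclass
class WindowProfile:
    window: int
    step: int
    windows: list[Window]

    def total(self) -> int:
        return sum(w.count for w in self.windows)

    def to_tsv(self) -> str:
        lines = ["start\tend\tmissense\tpartial"]
        for w in self.windows:
            lines.append(f"{w.start + 1}\t{w.end}\t{w.count}\t{'yes' if w.partial else 'no'}")
        return "\n".join(lines) + "\n"


def missense_positions(cds: str, reference: str) -> list[int]:
    """0-based positions where ``cds`` differs from ``reference`` and the
    single-base change in the reference codon is nonsynonymous.

    Codons with gaps (either sequence) are skipped; each differing position
    is judged by substituting that base alone into the reference codon.
    """
    if len(cds) != len(reference):
        raise ValueError("sequence and reference lengths differ")
    out = []
    for ci in range(len(reference) // 3):
        ref_codon = reference[ci * 3 : ci * 3 + 3]
        obs_codon = cds[ci * 3 : ci * 3 + 3]
        if "-" in ref_codon or "-" in obs_codon:
            continue
        for k in range(3):
            if ref_codon[k] == obs_codon[k]:
                continue
            mutated = ref_codon[:k] + obs_codon[k] + ref_codon[k + 1 :]
            if is_stop(mutated) or is_stop(ref_codon):
                continue
            if AA_OF[mutated] != AA_OF[ref_codon]:
                out.append(ci * 3 + k)
    return out


def missense_window_profile(
    cds_set: dict[str, str],
    reference_ancestor: str,
    window: int = 30,
    step: int = 20,
) -> WindowProfile:
    """Missense counts summed over all sequences per sliding window.

    Windows are anchored at CDS position 1 of the reference and step by
    ``step`` (default 30/20: consecutive windows overlap by 10 nt); the final
    partial window is retained and flagged. A changed nucleotide contributes
    to every window containing it.
    """
    length = len(reference_ancestor)
    positions: list[int] = []
    for seq in cds_set.values():
        positions.extend(missense_positions(seq, reference_ancestor))
    windows = []
    start = 0
    while start < length:
        end = min(start + window, length)
        count = sum(1 for p in positions if start <= p < end)
        windows.append(Window(start, end, count, partial=end - start < window))
        if end == length:
            break
        start += step
    if length < window and not windows:
        windows.append(Window(0, length, 0, partial=True))
    return WindowProfile(window, step, windows)
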