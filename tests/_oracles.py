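"""Independent brute-force oracles used by the equivalence test suites.

Each oracle recomputes a quantity by exhaustive enumeration, deliberately
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np

STANDARD_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(product(_BASES, repeat=3)):
    STANDARD_CODE[_a + _b + _c] = _AAS[_i]


def sw_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score by exhaustive path enumeration.

    Every alignment path is a sequence of match / delete / insert moves
    starting and reaching any cell; the running score is recorded at every
    prefix, so ending anywhere is free. Affine gaps: the first gapped column
    of a run costs gap_open, subsequent ones gap_extend. Adjacent gap runs in
    opposite directions are pruned (they cost two openings, always worse than
    a mismatch column under protein matrices). Exponential — short inputs only.
    """
    best = 0.0

    def extend(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a) and last not in ("i", "start"):
            extend(i + 1, j, score - (gap_extend if last == "d" else gap_open), "d")
        if j < len(b) and last not in ("d", "start"):
            extend(i, j + 1, score - (gap_extend if last == "i" else gap_open), "i")

    for i in range(len(a)):
        for j in range(len(b)):
            extend(i, j, 0.0, "start")
    return best


def fitch_min_score(children_of, root, leaf_states: dict, alphabet: str = "ACGT") -> int:
    """Exhaustive minimum parsimony score for one site on a rooted tree.

    ``children_of`` maps node id -> list of child ids (leaves absent);
    ``leaf_states`` maps leaf id -> state character.
    """
    internal = [n for n in children_of if children_of[n]]

    def cost(assign):
        total = 0
        for parent, kids in children_of.items():
            for kid in kids:
                ps = assign[parent]
                ks = leaf_states.get(kid, assign.get(kid))
                total += ps != ks
        return total

    best = None
    for combo in product(alphabet, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        c = cost(assign)
        if best is None or c < best:
            best = c
    return best


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon, enumerating
    the nine single-base mutations, stop targets excluded from the
    per-position denominator."""
    syn = 0.0
    for pos in range(3):
        s = v = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if STANDARD_CODE[alt] == "*":
                continue
            v += 1
            s += STANDARD_CODE[alt] == STANDARD_CODE[codon]
        if v:
            syn += s / v
    return syn, 3.0 - syn


def ng86_differences(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) observed differences averaged over stop-free pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    tot_s = tot_n = paths = 0
    for order in permutations(diffs):
        cur, s, n, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if STANDARD_CODE[nxt] == "*":
                ok = False
                break
            if STANDARD_CODE[nxt] == STANDARD_CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            tot_s += s
            tot_n += n
            paths += 1
    if paths == 0:
        return float("nan"), float("nan")
    return tot_s / paths, tot_n / paths


def substring_parsimony_best(
    seqs: dict[str, str], k: int, max_per_branch: int
) -> tuple[int, dict]:
    """Exhaustive substring parsimony for exactly three taxa on the rooted
    tree ((t1, t2), t3): enumerate every per-taxon k-mer occurrence and every
    internal labelling, vectorised over the 4**k label space.

    Returns (minimum total score over branch-feasible assignments, best
    assignment as {taxon: (pos, kmer)}).
    """
    taxa = list(seqs)
    assert len(taxa) == 3
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    code_of = {m: i for i, m in enumerate(kmers)}
    n = len(kmers)
    ham = np.zeros((n, n), dtype=np.int16)
    arr = np.array([list(m) for m in kmers])
    for i in range(n):
        ham[i] = (arr != arr[i]).sum(axis=1)

    occs = {
        t: [(i, seqs[t][i : i + k]) for i in range(len(seqs[t]) - k + 1)]
        for t in taxa
    }
    feas = ham <= max_per_branch
    best_score, best_assign = None, None
    for p1, m1 in occs[taxa[0]]:
        c1 = code_of[m1]
        for p2, m2 in occs[taxa[1]]:
            c2 = code_of[m2]
            # internal node x above (t1, t2); root y above (x, t3)
            sub = np.where(feas[:, c1], ham[:, c1], 9999) + np.where(
                feas[:, c2], ham[:, c2], 9999
            )
            for p3, m3 in occs[taxa[2]]:
                c3 = code_of[m3]
                # root label y: cost = min_x (sub[x] + d(y,x) feasible) + d(y,c3)
                trans = np.where(feas, ham, 9999)
                via_x = (sub[None, :] + trans).min(axis=1)
                total = via_x + np.where(feas[:, c3], ham[:, c3], 9999)
                score = int(total.min())
                if best_score is None or score < best_score:
                    best_score = score
                    best_assign = {taxa[0]: (p1, m1), taxa[1]: (p2, m2), taxa[2]: (p3, m3)}
    return best_score, best_assign
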