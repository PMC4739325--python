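"""Independent oracles used by the test suite. These deliberately avoid the
implementation's code paths: the alignment oracle is a numpy lazy-E DP (itself
validated against a dictionary-free brute-force Python DP), the dN/dS oracle
re-derives site and pathway counts from Biopython's translation, and the
Fisher oracle sums hypergeometric tail probabilities from math.comb."""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from Bio.Seq import Seq

NEG = -(10**9)


def brute_sw_affine(a: str, b: str, match: int, mismatch: int, open_: int, ext: int) -> int:
    """Plain-Python affine local alignment (gap cost open + ext*L)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ext, H[i][j - 1] - open_ - ext)
            F[i][j] = max(F[i - 1][j] - ext, H[i - 1][j] - open_ - ext)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def numpy_sw_affine(a: str, b: str, match: int, mismatch: int, open_: int, ext: int) -> int:
    """Row-vectorized affine local alignment score (lazy-E resolution: the
    within-row gap state never needs to chain through another same-row gap,
    because two gaps cost more than one covering the same span)."""
    codes = {c: i for i, c in enumerate("ACGTN")}
    av = np.array([codes[c] for c in a])
    bv = np.array([codes[c] for c in b])
    m = bv.size
    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    jj = np.arange(1, m + 1, dtype=np.int64)
    for i in range(av.size):
        s = np.where((bv == av[i]) & (av[i] < 4), match, -mismatch)
        diag = H[:-1] + s
        F[1:] = np.maximum(F[1:] - ext, H[1:] - open_ - ext)
        H0 = np.maximum.reduce([np.zeros(m, dtype=np.int64), diag, F[1:]])
        Hrow = np.concatenate([[0], H0])
        # E[j] = max_{j'<j} Hrow[j'] - open - ext*(j-j')
        run = np.maximum.accumulate(Hrow[:-1] + ext * np.arange(m))
        E = run - open_ - ext * jj
        Hnew = np.maximum(Hrow[1:], E)
        H = np.concatenate([[0], Hnew])
        best = max(best, int(Hnew.max(initial=0)))
    return best


# ---------------------------------------------------------------------------
# Nei-Gojobori oracle


def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=1))


def ng_sites_oracle(codon: str):
    n = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _aa(alt) != _aa(codon):
                n += 1 / 3
    return n, 3 - n


def ng_counts_oracle(seq_a: str, seq_b: str):
    """(N, S, Nd, Sd) by explicit path enumeration with Biopython translation."""
    N = S = Nd = Sd = 0.0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        for c in (ca, cb):
            n, s = ng_sites_oracle(c)
            N += n / 2
            S += s / 2
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if not diff:
            continue
        paths = list(permutations(diff))
        nd = sd = 0.0
        for order in paths:
            cur = ca
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
        Nd += nd / len(paths)
        Sd += sd / len(paths)
    return N, S, Nd, Sd


# ---------------------------------------------------------------------------
# Fisher two-sided oracle


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact P: sum of hypergeometric pmfs <= pmf(observed),
    computed from math.comb."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    ntot = row1 + row2

    def pmf(x: int) -> float:
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(ntot, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# single-origin parsimony oracle by exhaustive labeling enumeration


def lca_enumeration_oracle(children: dict, root, leaves: dict):
    """Exhaustive minimum-change enumeration over all presence/absence
    labelings of internal nodes in which the present nodes form a connected
    subtree containing every present leaf (single origin). Returns the most
    recent (deepest) origin among minimum-change labelings.

    children: node -> list of child nodes (leaves absent from the map);
    leaves: leaf name -> present flag.
    """
    internals = sorted(children)
    present_leaves = {k for k, v in leaves.items() if v}
    if not present_leaves:
        raise ValueError("all absent")
    depth = {}

    def set_depth(node, d):
        depth[node] = d
        for ch in children.get(node, []):
            set_depth(ch, d + 1)

    set_depth(root, 0)

    def parents():
        par = {}
        for node, chs in children.items():
            for ch in chs:
                par[ch] = node
        return par

    par = parents()
    best_cost = None
    best_origins = []
    for bits in range(2 ** len(internals)):
        state = {leaf: leaves[leaf] for leaf in leaves}
        for idx, node in enumerate(internals):
            state[node] = bool(bits >> idx & 1)
        # changes on edges
        cost = sum(
            1
            for ch, p in par.items()
            if state[ch] != state[p]
        )
        present_nodes = {n for n, v in state.items() if v}
        if not present_nodes:
            continue
        # connectivity of present nodes (single origin)
        origin_candidates = [
            n for n in present_nodes if n not in par or not state[par[n]]
        ]
        if len(origin_candidates) != 1:
            continue
        origin = origin_candidates[0]

        def subtree_ok(node):
            return all(
                (leaves[n] if n in leaves else state[n]) in (True, False)
                for n in [node]
            )

        # origin must be an ancestor of (or equal to) every present leaf
        def is_ancestor(anc, node):
            while node in par:
                if node == anc:
                    return True
                node = par[node]
            return node == anc

        if not all(is_ancestor(origin, leaf) for leaf in present_leaves):
            continue
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_origins = [origin]
        elif cost == best_cost:
            best_origins.append(origin)
    # most recent ancestor tie-break
    best_origins.sort(key=lambda n: (-depth[n], str(n)))
    return best_origins[0], len(set(best_origins)) > 1
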