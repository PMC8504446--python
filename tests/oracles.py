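"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration / O(n^2) counting) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np

from plastdeg.ancestral import er_transition_matrix

STOPS = {"TAA", "TAG", "TGA"}
_CODE = {}  # bacterial/plastid code, built from Biopython once
from Bio.Data import CodonTable as _CT

_CODE.update(_CT.unambiguous_dna_by_id[11].forward_table)


def brute_mk_loglik(tree, character, mu, k):
    """Likelihood by summation over every internal-node state assignment."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, assign)}
        for leaf in tree.leaves():
            st[id(leaf)] = character[leaf.name]
        p = 1.0 / k
        for n in tree.postorder():
            if n.parent is None:
                continue
            P = er_transition_matrix(mu, tree.branch_length(n), k)
            p *= P[st[id(n.parent)], st[id(n)]]
        total += p
    return np.log(total)


def brute_mk_marginal(tree, character, mu, k, node):
    """P(node = s | tips) by enumeration."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    tot = np.zeros(k)
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, assign)}
        for leaf in tree.leaves():
            st[id(leaf)] = character[leaf.name]
        p = 1.0 / k
        for n in tree.postorder():
            if n.parent is None:
                continue
            P = er_transition_matrix(mu, tree.branch_length(n), k)
            p *= P[st[id(n.parent)], st[id(n)]]
        tot[st[id(node)]] += p
    return tot / tot.sum()


def brute_dollo_min_events(tree, character):
    """Minimum event count over all single-origin internal assignments."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = None
    for assign in itertools.product((0, 1), repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, assign)}
        for leaf in tree.leaves():
            st[id(leaf)] = character[leaf.name]
        origins = 1 if st[id(tree.root)] == 1 else 0
        reversals = 0
        for n in tree.postorder():
            if n.parent is None:
                continue
            a, b = st[id(n.parent)], st[id(n)]
            if a == 0 and b == 1:
                origins += 1
            elif a == 1 and b == 0:
                reversals += 1
        if origins > 1:
            continue
        events = origins + reversals
        if best is None or events < best:
            best = events
    return best


def brute_u_statistic(x, y):
    """Pairwise ordering count: #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def brute_u_exact_pvalue(x, y):
    """Two-sided exact p by enumerating every group relabeling."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = brute_u_statistic(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        grp = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in grp]
        us.append(brute_u_statistic(xs, ys))
    us = np.array(us)
    lo = np.mean(us <= u_obs + 1e-12)
    hi = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


def brute_spearman(x, y):
    """Rank-then-Pearson, with explicit average ranks."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_ng86_pair_diffs(codon_a, codon_b):
    """Pathway-averaged (Sd, Nd) for one codon pair, stop paths excluded
    (falling back to all paths when every pathway crosses a stop)."""

    def one_direction(ca, cb, allow_stops):
        diff = [j for j in range(3) if ca[j] != cb[j]]
        if not diff:
            return 0.0, 0.0, True
        paths = []
        for order in itertools.permutations(diff):
            cur, syn, ok = ca, 0.0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOPS and not allow_stops:
                    ok = False
                    break
                if nxt not in STOPS and cur not in STOPS and _CODE[nxt] == _CODE[cur]:
                    syn += 1.0
                cur = nxt
            if ok:
                paths.append(syn)
        if not paths:
            return 0.0, 0.0, False
        s = sum(paths) / len(paths)
        return s, len(diff) - s, True

    sd = nd = 0.0
    for ca, cb in ((codon_a, codon_b), (codon_b, codon_a)):
        s, n, ok = one_direction(ca, cb, allow_stops=False)
        if not ok:
            s, n, _ = one_direction(ca, cb, allow_stops=True)
        sd += s / 2
        nd += n / 2
    return sd, nd
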