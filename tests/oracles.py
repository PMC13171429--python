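"""Independent brute-force oracles used by the test suite.

Each oracle recomputes its quantity by direct enumeration, sharing no code
with the package implementation: segmentation re-scans base counts at every
candidate split, the codon oracle re-derives site fractions and pathway
counts via Biopython translation, and the Mk oracle sums the likelihood over
every internal state assignment.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
from Bio.Seq import Seq

from vertitrace.trait_evo import transition_matrix

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def brute_segment(seq: str, t0: float, min_len: int) -> list[int]:
    """Recursive segmentation that recounts bases from scratch at every split."""
    arr = np.array([_ENC[b] for b in seq], dtype=np.int64)

    def best(lo, hi):
        best_pos, best_delta = None, -math.inf
        for i in range(lo + min_len, hi - min_len + 1):
            cl = np.bincount(arr[lo:i], minlength=5)[:4].astype(float)
            cr = np.bincount(arr[i:hi], minlength=5)[:4].astype(float)
            nl, nr = cl.sum(), cr.sum()
            if nl == 0 or nr == 0:
                continue
            d = (
                (cl**2).sum() / nl
                + (cr**2).sum() / nr
                - ((cl + cr) ** 2).sum() / (nl + nr)
            )
            if d > best_delta:
                best_pos, best_delta = i, d
        return best_pos, best_delta

    out: list[int] = []
    stack = [(0, len(seq))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_len:
            continue
        pos, delta = best(lo, hi)
        if pos is None or delta < t0:
            continue
        out.append(pos)
        stack.append((lo, pos))
        stack.append((pos, hi))
    return sorted(out)


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=1))


def _site_s(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        alts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        alts = [a for a in alts if _aa(a) != "*"]
        if alts:
            s += sum(_aa(a) == _aa(codon) for a in alts) / len(alts)
    return s


def _path_sd_nd(c1: str, c2: str):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    totals, n_ok = [0.0, 0.0], 0
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals[0] += sd
            totals[1] += nd
            n_ok += 1
    if n_ok == 0:
        return None
    return totals[0] / n_ok, totals[1] / n_ok


def brute_ng86(row1: str, row2: str) -> dict:
    """Pairwise NG86 recomputed from first principles via Biopython translation."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(row1), 3):
        c1, c2 = row1[i : i + 3], row2[i : i + 3]
        if set(c1 + c2) - set("ACGT"):
            continue
        if _aa(c1) == "*" or _aa(c2) == "*":
            continue
        counts = _path_sd_nd(c1, c2)
        if counts is None:
            continue
        S += (_site_s(c1) + _site_s(c2)) / 2.0
        N += (3.0 - _site_s(c1) + 3.0 - _site_s(c2)) / 2.0
        Sd += counts[0]
        Nd += counts[1]
    if S == 0 and N == 0:
        raise ValueError("no comparable columns")
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return None if (4 / 3) * p >= 1 else -0.75 * math.log(1 - (4 / 3) * p)

    dS, dN = jc(pS), jc(pN)
    if pS == 0 and pN > 0:
        status, omega = "undefined_pS0", None
    elif dS is None or dN is None:
        status, omega = "saturated", None
    elif dS == 0 or dN == 0:
        status, omega = "filtered_dN0_or_dS0", None
    else:
        status, omega = "ok", dN / dS
    return {
        "S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
        "dS": dS, "dN": dN, "omega": omega, "status": status,
    }


def brute_mk_loglik(tree, traits, q01: float, q10: float, prior=(0.5, 0.5)) -> float:
    """Mk likelihood by enumeration over all internal state assignments."""
    nodes = list(tree.preorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internals)):
        st = {n: s for n, s in zip(internals, assign)}
        for lf in tree.leaf_node_iter():
            st[lf] = traits[lf.taxon.label]
        p = prior[st[tree.seed_node]]
        for n in nodes:
            for c in n.child_nodes():
                P = transition_matrix(q01, q10, c.edge.length or 0.0)
                p *= P[st[n], st[c]]
        total += p
    return math.log(total)


def partition_of(assignment: dict) -> set[frozenset]:
    """Cluster assignment (id -> group) as a set of frozensets for comparison."""
    groups: dict = {}
    for k, g in assignment.items():
        groups.setdefault(g, set()).add(k)
    return {frozenset(v) for v in groups.values()}
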