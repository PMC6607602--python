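"""Independent reference implementations used only by the tests.

These recompute the package's core quantities by different routes —
memoized recursion instead of an iterative matrix fill, explicit
combinatorial sums instead of scipy, literal double loops instead of
dictionary passes — so agreement is evidence of correctness rather than
of shared bugs.  All alignment comparisons use integer-valued scoring
parameters, for which floating-point sums are exact in either order.
"""

from __future__ import annotations

import math
from functools import lru_cache

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def oracle_pair_score(a: str, b: str, params) -> float:
    if (a, b) in _WC:
        return params.match_wc
    if (a, b) in _GU:
        return params.match_gu
    return params.mismatch


def oracle_column_energy(a: str, b: str, params) -> float:
    if a == "-" or b == "-":
        return params.energy_other
    pair = frozenset((a, b))
    if pair == frozenset("GC"):
        return params.energy_gc
    if pair == frozenset("AU"):
        return params.energy_au
    if pair == frozenset("GU"):
        return params.energy_gu
    return params.energy_other


def oracle_scan(mirna, target: str, params):
    """Exhaustive local-alignment site prediction by memoized recursion.

    Enumerates, for every cell, the best alignment ending there via a
    three-state recursion with explicit gap-length enumeration, applies
    the same greedy non-overlapping selection (best score, ties by
    smaller start), then the energy and strict-seed filters.  Returns
    tuples (start, end, score, energy, alignment, seed_strict) sorted by
    start — directly comparable with ``scan_pair`` output.
    """
    m = len(mirna.residues)
    mir_rev = mirna.residues[::-1]
    n = len(target)
    banned: set[int] = set()
    out = []

    def seed_scale(i0: int) -> float:
        pos = m - i0  # 1-based 5' position of reversed-miRNA row i0
        return params.seed_scale if params.seed_start <= pos <= params.seed_end else 1.0

    while True:

        @lru_cache(maxsize=None)
        def M(i: int, j: int) -> float:
            # best alignment ending with mir_rev[i-1] paired to target[j-1]
            if i < 1 or j < 1 or (j - 1) in banned:
                return -math.inf
            s = seed_scale(i - 1) * oracle_pair_score(mir_rev[i - 1], target[j - 1], params)
            return s + max(0.0, H(i - 1, j - 1))

        @lru_cache(maxsize=None)
        def E(i: int, j: int) -> float:
            # best alignment ending with target[j-1] opposite a gap
            if j < 1 or (j - 1) in banned:
                return -math.inf
            best = -math.inf
            for g in range(1, j + 1):
                if any((j - 1 - x) in banned for x in range(g)):
                    break
                v = H(i, j - g) + params.gap_open + params.gap_extend * (g - 1)
                best = max(best, v)
            return best

        @lru_cache(maxsize=None)
        def F(i: int, j: int) -> float:
            # best alignment ending with mir_rev[i-1] opposite a gap
            # (claimed target columns sever every state, gaps included)
            if i < 1 or (j >= 1 and (j - 1) in banned):
                return -math.inf
            best = -math.inf
            for g in range(1, i + 1):
                v = H(i - g, j) + params.gap_open + params.gap_extend * (g - 1)
                best = max(best, v)
            return best

        def H(i: int, j: int) -> float:
            if i < 1 or j < 1 or (j - 1) in banned:
                return 0.0
            return max(0.0, M(i, j), E(i, j), F(i, j))

        best = -math.inf
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                best = max(best, H(i, j))
        if best < params.score_threshold:
            break

        def trace(i: int, j: int):
            cols = []
            state = "H"
            while True:
                if state == "H":
                    h = H(i, j)
                    if h == 0.0:
                        break
                    if h == M(i, j):
                        cols.append(("pair", i - 1, j - 1))
                        i, j = i - 1, j - 1
                    elif h == E(i, j):
                        state = "E"
                    else:
                        state = "F"
                elif state == "E":
                    cols.append(("tgap", -1, j - 1))
                    if E(i, j) == H(i, j - 1) + params.gap_open:
                        state = "H"
                    j -= 1
                else:
                    cols.append(("mgap", i - 1, -1))
                    if F(i, j) == H(i - 1, j) + params.gap_open:
                        state = "H"
                    i -= 1
            cols.reverse()
            return cols

        chosen = None
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                if H(i, j) != best:
                    continue
                cols = trace(i, j)
                tpos = [tj for _, _, tj in cols if tj >= 0]
                mpos = [mi for _, mi, _ in cols if mi >= 0]
                key = (min(tpos), max(tpos) + 1, min(mpos), max(mpos) + 1)
                if chosen is None or key < chosen[0]:
                    chosen = (key, cols)
        (ts, te, _, _), cols = chosen

        mir_line, pair_line, tgt_line = [], [], []
        for kind, mi, tj in cols:
            if kind == "pair":
                mir_line.append(mir_rev[mi])
                tgt_line.append(target[tj])
                pr = (mir_rev[mi], target[tj])
                pair_line.append("|" if pr in _WC else ":" if pr in _GU else " ")
            elif kind == "mgap":
                mir_line.append(mir_rev[mi])
                tgt_line.append("-")
                pair_line.append(" ")
            else:
                mir_line.append("-")
                tgt_line.append(target[tj])
                pair_line.append(" ")
        aln = ("".join(mir_line), "".join(pair_line), "".join(tgt_line))
        energy = sum(oracle_column_energy(a, b, params) for a, b in zip(aln[0], aln[2]))

        seed_positions = set(range(params.seed_start, params.seed_end + 1))
        seed_idx = []
        strict = True
        for idx, (kind, mi, tj) in enumerate(cols):
            if kind == "pair" and (m - mi) in seed_positions:
                if (mir_rev[mi], target[tj]) not in _WC:
                    strict = False
                seed_idx.append(idx)
        if len(seed_idx) != len(seed_positions):
            strict = False
        elif strict:
            strict = max(seed_idx) - min(seed_idx) == len(seed_positions) - 1

        out.append((ts, te, best, energy, aln, strict))
        banned |= set(range(ts, te))

    kept = [
        s
        for s in out
        if s[3] <= params.energy_threshold and (not params.strict or s[5])
    ]
    return sorted(kept, key=lambda s: s[0])


def oracle_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability by explicit combinatorial sum."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def oracle_ct(summaries, interactions):
    """Brute-force double loop over all (summary, interaction) pairs."""
    ct: dict[str, int] = {}
    for it in interactions:
        for s in summaries:
            if s.mirna_id == it.mirna_id:
                ct[it.gene] = ct.get(it.gene, 0) + s.nbs
    return ct
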