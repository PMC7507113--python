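"""Independent brute-force oracles used to verify the implementation.

Each oracle is deliberately naive and structured differently from the
code it checks: codon-by-codon frame scanning for ORFs, substring
enumeration with plain global alignment for local alignment scores,
exhaustive path DFS for alignment semantics, and textbook formulas for
the chi-square decomposition.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = str.maketrans("ACGTN", "TGCAN")


def orf_scan(seq: str, table: int, min_len: int) -> list[tuple[int, int, str]]:
    """Six-frame codon-by-codon ORF scan; (start, end, strand) tuples."""
    stops = {11: {"TAA", "TAG", "TGA"}, 25: {"TAA", "TAG"}}[table]
    L = len(seq)
    out = []
    for strand, s in (("+", seq), ("-", seq.translate(_COMP)[::-1])):
        for f in range(3):
            start = None
            i = f
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                if "N" in codon:
                    i += 3
                    continue
                if codon == "ATG" and start is None:
                    start = i
                if codon in stops:
                    if start is not None and (i + 3 - start) >= min_len:
                        if strand == "+":
                            out.append((start, i + 3, strand))
                        else:
                            out.append((L - (i + 3), L - start, strand))
                    start = None
                i += 3
    return sorted(out)


def local_align_score(q: str, s: str, sub, gap_open: float, gap_ext: float
                      ) -> float:
    """Best local score = max over substring pairs of global affine score."""

    @lru_cache(maxsize=None)
    def glob(qs: str, ss: str) -> float:
        # plain iterative global affine alignment of two short strings
        n, m = len(qs), len(ss)
        NEG = float("-inf")
        M = [[NEG] * (m + 1) for _ in range(n + 1)]
        X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
        Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
        M[0][0] = 0.0
        for i in range(1, n + 1):
            X[i][0] = -gap_open - (i - 1) * gap_ext
        for j in range(1, m + 1):
            Y[0][j] = -gap_open - (j - 1) * gap_ext
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                d = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                M[i][j] = d + sub[qs[i - 1]][ss[j - 1]]
                X[i][j] = max(M[i - 1][j] - gap_open,
                              X[i - 1][j] - gap_ext,
                              Y[i - 1][j] - gap_open)
                Y[i][j] = max(M[i][j - 1] - gap_open,
                              Y[i][j - 1] - gap_ext,
                              X[i][j - 1] - gap_open)
        return max(M[n][m], X[n][m], Y[n][m])

    best = 0.0
    for i1 in range(len(q)):
        for i2 in range(i1 + 1, len(q) + 1):
            for j1 in range(len(s)):
                for j2 in range(j1 + 1, len(s) + 1):
                    best = max(best, glob(q[i1:i2], s[j1:j2]))
    glob.cache_clear()
    return best


def local_align_paths(q: str, s: str, sub, gap_open: float, gap_ext: float
                      ) -> tuple[float, int]:
    """Exhaustive DFS over *all* local alignment paths (tiny inputs only).

    Returns (best score, longest column count among best-scoring paths).
    """
    best = [0.0, 0]

    def walk(i, j, score, length, last):
        if length > 0:
            if score > best[0] or (score == best[0] and length > best[1]):
                best[0], best[1] = score, length
        if i < len(q) and j < len(s):
            walk(i + 1, j + 1, score + sub[q[i]][s[j]], length + 1, "M")
        if i < len(q):
            cost = gap_ext if last == "X" else gap_open
            walk(i + 1, j, score - cost, length + 1, "X")
        if j < len(s):
            cost = gap_ext if last == "Y" else gap_open
            walk(i, j + 1, score - cost, length + 1, "Y")

    for i in range(len(q) + 1):
        for j in range(len(s) + 1):
            walk(i, j, 0.0, 0, "")
    return best[0], best[1]


def chisq_textbook(table):
    """Plain-formula chi-square decomposition: (X2, df, E, residuals, pct)."""
    r = len(table)
    c = len(table[0])
    rows = [sum(table[i]) for i in range(r)]
    cols = [sum(table[i][j] for i in range(r)) for j in range(c)]
    N = sum(rows)
    E = [[rows[i] * cols[j] / N for j in range(c)] for i in range(r)]
    resid = [[(table[i][j] - E[i][j]) / E[i][j] ** 0.5 for j in range(c)]
             for i in range(r)]
    x2 = sum(resid[i][j] ** 2 for i in range(r) for j in range(c))
    pct = [[100.0 * resid[i][j] ** 2 / x2 if x2 > 0 else 0.0
            for j in range(c)] for i in range(r)]
    return x2, (r - 1) * (c - 1), E, resid, pct


def ranksum_enumeration(x, y):
    """Exact two-sided rank-sum p by full enumeration over assignments."""
    from itertools import combinations

    pooled = sorted(list(x) + list(y))
    # midranks
    ranks = {}
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[j + 1] == pooled[i]:
            j += 1
        mid = (i + 1 + j + 1) / 2.0
        ranks.setdefault(pooled[i], mid)
        i = j + 1
    rank_list = [ranks[v] for v in pooled]
    obs = sum(ranks[v] for v in x)   # ties share the same midrank
    n, N = len(x), len(pooled)
    mu = n * (N + 1) / 2.0
    dev = abs(obs - mu)
    count = total = 0
    for idx in combinations(range(N), n):
        w = sum(rank_list[k] for k in idx)
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / total
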