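"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles (exhaustive
enumeration, closed form, or a plain triple-loop dynamic program) and is
deliberately written without reference to the package implementation.
"""

from __future__ import annotations

import itertools
from math import comb

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Smith–Waterman, plain triple loop with explicit traceback
# ---------------------------------------------------------------------------

def sw_align(query: str, ref: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """(score, ref_start, ref_end, matches, columns) of the best local
    alignment, 1-based; None if no positive score."""
    nq, nr = len(query), len(ref)
    H = [[0] * (nr + 1) for _ in range(nq + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, nq + 1):
        qi = query[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, nr + 1):
            s = match if ref[j - 1] == qi else mismatch
            v = prev[j - 1] + s
            if prev[j] + gap > v:
                v = prev[j] + gap
            if row[j - 1] + gap > v:
                v = row[j - 1] + gap
            row[j] = v if v > 0 else 0
            if row[j] > best:
                best, bi, bj = row[j], i, j
    if best <= 0:
        return None
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if query[i - 1] == ref[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += query[i - 1] == ref[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i][j - 1] + gap:
            columns += 1
            j -= 1
        elif H[i][j] == H[i - 1][j] + gap:
            columns += 1
            i -= 1
        else:
            break
    return best, j + 1, bj, matches, columns


def read_counts_oracle(read: str, pseudo_seq: str, junction_index: int,
                       min_cover_frac: float = 0.8, min_span: int = 10,
                       min_identity: float = 0.95) -> bool:
    """Full-DP decision: does the read satisfy the BSJ counting rule?"""
    for q in (read, rc(read)):
        aln = sw_align(q, pseudo_seq)
        if aln is None:
            continue
        _, rs, re_, matches, columns = aln
        cover = re_ - rs + 1
        if cover < min_cover_frac * len(pseudo_seq):
            continue
        if columns and matches / columns < min_identity:
            continue
        if junction_index - rs + 1 >= min_span and re_ - junction_index >= min_span:
            return True
    return False


# ---------------------------------------------------------------------------
# Fisher exact test by hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed FET p: sum of hypergeometric probabilities of all
    tables with the same margins that are no more probable than the
    observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum by full enumeration of rank assignments
# ---------------------------------------------------------------------------

def wrst_exact_oracle(x, y, alternative: str = "greater") -> float:
    """P-value by enumerating all C(n1+n2, n1) group assignments of the
    pooled (tie-free) values and comparing rank sums."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rsum = sum(i + 1 for i in combo)
        total += 1
        if alternative == "greater" and rsum >= obs:
            count += 1
        elif alternative == "less" and rsum <= obs:
            count += 1
        elif alternative == "two-sided":
            mu = n1 * (len(pooled) + 1) / 2
            if abs(rsum - mu) >= abs(obs - mu) - 1e-9:
                count += 1
    return count / total


# ---------------------------------------------------------------------------
# Benjamini–Hochberg step-up
# ---------------------------------------------------------------------------

def bh_oracle(pvals) -> list[float]:
    """Adjusted values from the literal step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# reverse-complement match pairs by diagonal scanning
# ---------------------------------------------------------------------------

def rc_matches_oracle(a: str, b: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal exact matches ≥ min_len between a and revcomp(b),
    found by walking every diagonal and recording runs of equality."""
    rb = rc(b)
    out = set()
    for d in range(-(len(rb) - 1), len(a)):
        i = max(0, d)
        j = i - d
        run = 0
        while i <= len(a) and j <= len(rb):
            eq = i < len(a) and j < len(rb) and a[i] == rb[j]
            if eq:
                run += 1
            else:
                if run >= min_len:
                    out.add((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
    return out
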