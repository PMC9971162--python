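"""Local alignment primitives for BSJ read matching.

A dependency-free Smith–Waterman aligner (match +1, mismatch −1,
gap −2 by default) with a numpy row-scan recurrence: the horizontal
(gap-in-reference) dependency inside a row is resolved with a running
prefix maximum, so each DP row is a vectorised operation.  Traceback
recovers the aligned reference interval, the number of matches and the
number of aligned columns, which is what the read-counting criteria
(coverage, identity, junction span) need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    ref_start: int   # 1-based inclusive on the reference
    ref_end: int
    query_start: int
    query_end: int
    matches: int     # identical aligned bases
    columns: int     # aligned columns (matches + mismatches + gaps)


_BASE_ORD = np.frombuffer(b"\x00" * 256, dtype=np.uint8).copy()
for _i, _b in enumerate(b"ACGTN"):
    _BASE_ORD[_b] = _i + 1


def _encode(seq: str) -> np.ndarray:
    return _BASE_ORD[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _sw_python(q: np.ndarray, r: np.ndarray, match: int, mismatch: int, g: int,
               ) -> tuple[int, int, int, int, int, int, int]:
    nq, nr = len(q), len(r)
    H = np.zeros((nq + 1, nr + 1), dtype=np.int32)
    gidx = g * np.arange(nr, dtype=np.int32)
    for i in range(1, nq + 1):
        sub = np.where(r == q[i - 1], match, mismatch).astype(np.int32)
        base = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] - g)
        np.maximum(base, 0, out=base)
        # propagate horizontal gaps with a prefix max over base[k] + g*k
        ext = np.maximum.accumulate(base + gidx) - gidx
        H[i, 1:] = np.maximum(np.maximum(base, ext), 0)
    best = int(H.max())
    if best <= 0:
        return (0, 0, 0, 0, 0, 0, 0)
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    matches = columns = 0
    qe, re_ = int(i), int(j)
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if q[i - 1] == r[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += int(q[i - 1] == r[j - 1])
            columns += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i, j - 1] - g:
            columns += 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - g:
            columns += 1
            i -= 1
        else:  # reached a fresh local start
            break
    return (best, int(j) + 1, re_, int(i) + 1, qe, matches, columns)


def _make_sw_numba():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a soft dependency
        return None

    @njit(cache=False)
    def _sw(q, r, match, mismatch, g):  # pragma: no cover - jitted
        nq, nr = len(q), len(r)
        H = np.zeros((nq + 1, nr + 1), dtype=np.int32)
        best = 0
        bi = bj = 0
        for i in range(1, nq + 1):
            qi = q[i - 1]
            for j in range(1, nr + 1):
                s = match if r[j - 1] == qi else mismatch
                v = H[i - 1, j - 1] + s
                if H[i - 1, j] - g > v:
                    v = H[i - 1, j] - g
                if H[i, j - 1] - g > v:
                    v = H[i, j - 1] - g
                if v < 0:
                    v = 0
                H[i, j] = v
                if v > best:
                    best, bi, bj = v, i, j
        if best <= 0:
            return (0, 0, 0, 0, 0, 0, 0)
        i, j = bi, bj
        matches = 0
        columns = 0
        while i > 0 and j > 0 and H[i, j] > 0:
            s = match if q[i - 1] == r[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if q[i - 1] == r[j - 1]:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
            elif H[i, j] == H[i, j - 1] - g:
                columns += 1
                j -= 1
            elif H[i, j] == H[i - 1, j] - g:
                columns += 1
                i -= 1
            else:
                break
        return (best, j + 1, bj, i + 1, bi, matches, columns)

    return _sw


_sw_jit = None
_sw_jit_tried = False


def local_align(query: str, ref: str, match: int = 1, mismatch: int = -1,
                gap: int = -2) -> LocalAlignment | None:
    """Best local alignment of query against ref; None if no positive score."""
    global _sw_jit, _sw_jit_tried
    if not query or not ref:
        return None
    q = _encode(query)
    r = _encode(ref)
    if not _sw_jit_tried:
        _sw_jit_tried = True
        _sw_jit = _make_sw_numba()
    core = _sw_jit if _sw_jit is not None else _sw_python
    best, rs, re_, qs, qe, matches, columns = core(q, r, match, mismatch, -gap)
    if best <= 0:
        return None
    return LocalAlignment(int(best), int(rs), int(re_), int(qs), int(qe),
                          int(matches), int(columns))


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class KmerIndex:
    """Exact k-mer index over a collection of named sequences."""

    def __init__(self, seqs: dict[str, str], k: int):
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in seqs.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i:i + k], []).append((name, i))

    def hits(self, seq: str, step: int = 1) -> list[tuple[str, int, int]]:
        """(name, ref_pos0, query_pos0) seed hits for every step-th k-mer."""
        out = []
        for qpos in range(0, len(seq) - self.k + 1, step):
            for name, rpos in self._index.get(seq[qpos:qpos + self.k], ()):
                out.append((name, rpos, qpos))
        return out

    def names_with_seed(self, seq: str, step: int = 1) -> set[str]:
        out: set[str] = set()
        for qpos in range(0, len(seq) - self.k + 1, step):
            for name, _ in self._index.get(seq[qpos:qpos + self.k], ()):
                out.add(name)
        return out
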