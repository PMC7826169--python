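"""Independent reference implementations used only to check the package.

These deliberately re-derive the same quantities by different routes:
quartiles/fences by explicit sort-and-interpolate arithmetic, and the
affine-gap alignment by a row-vectorised dynamic program with a prefix-scan
for the horizontal gap state (the production code uses a scalar
cell-by-cell recurrence), plus a tiny recursive scorer for short strings.
"""

from __future__ import annotations

import functools
import math

import numpy as np

from corecrunch.homology import _alignment_params, _encode

NEG = -(10 ** 15)


def brute_quartiles(values):
    s = sorted(values)
    n = len(s)

    def q(p):
        pos = p * (n - 1)
        lo = math.floor(pos)
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return s[lo] + (s[hi] - s[lo]) * frac

    return q(0.25), q(0.75)


def brute_fences(values):
    q1, q3 = brute_quartiles(values)
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def oracle_align_stats(a: str, b: str, alphabet: str = "protein"):
    """(score, identical_pairs, columns) by an independent Gotoh formulation.

    Forward pass is vectorised per row; the within-row gap state is obtained
    with a running-maximum prefix scan.  Traceback applies the same
    deterministic tie priority the production aligner documents (match state
    first, then gap-in-b, then gap-in-a; gap-open predecessor before
    gap-extend).
    """
    if b < a:
        a, b = b, a
    sub, go, ge, amb = _alignment_params(alphabet)
    ac = _encode(a)
    bc = _encode(b)
    n, m = len(ac), len(bc)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    M[0, 0] = 0
    Ix[1:, 0] = -(go + np.arange(n, dtype=np.int64) * ge)
    Iy[0, 1:] = -(go + np.arange(m, dtype=np.int64) * ge)
    j_idx = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        srow = sub[ac[i - 1], bc]
        prev = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = np.where(prev > NEG, prev + srow, NEG)
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge)
        # Iy[i, j] = max_{1<=k<=j} M[i, k-1] - go - (j-k)*ge, via prefix scan
        c = M[i, :-1] - go + j_idx * ge
        Iy[i, 1:] = np.maximum.accumulate(c) - j_idx * ge

    i, j = n, m
    score = max(M[n, m], Ix[n, m], Iy[n, m])
    if M[n, m] == score:
        state = 0
    elif Ix[n, m] == score:
        state = 1
    else:
        state = 2
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if state == 0:
            columns += 1
            ai, bj = ac[i - 1], bc[j - 1]
            if ai == bj and not amb[ai]:
                matches += 1
            prev = M[i, j] - sub[ai, bj]
            if M[i - 1, j - 1] == prev:
                state = 0
            elif Ix[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            columns += 1
            v = Ix[i, j]
            state = 0 if M[i - 1, j] == v + go else 1
            i -= 1
        else:
            columns += 1
            v = Iy[i, j]
            state = 0 if M[i, j - 1] == v + go else 2
            j -= 1
    return int(score), int(matches), int(columns)


def recursive_alignment_score(a: str, b: str, alphabet: str = "protein") -> int:
    """Optimal affine-gap global alignment score by plain recursion with memo.

    Only suitable for short strings; the three states mirror the Gotoh
    automaton (0 = match state, 1 = gap in b, 2 = gap in a; a gap of length
    k costs open + (k-1)*extend, and gap states never chain into each
    other's opposite directly).
    """
    sub, go, ge, _ = _alignment_params(alphabet)
    ac = _encode(a)
    bc = _encode(b)

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> int:
        if i == 0 and j == 0:
            return 0 if state == 0 else NEG
        options = []
        if state == 0 and i > 0 and j > 0:
            s = int(sub[ac[i - 1], bc[j - 1]])
            options = [best(i - 1, j - 1, st) + s for st in (0, 1, 2)]
        elif state == 1 and i > 0:
            options = [best(i - 1, j, 0) - go, best(i - 1, j, 1) - ge]
        elif state == 2 and j > 0:
            options = [best(i, j - 1, 0) - go, best(i, j - 1, 2) - ge]
        return max(options) if options else NEG

    return max(best(len(ac), len(bc), st) for st in (0, 1, 2))
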