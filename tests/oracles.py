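"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own search strategies: the dispersed
oracle enumerates every (anti-)diagonal of the self-comparison matrix, and
the NG86 oracle enumerates mutational pathways directly.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP_TBL = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP_TBL[a] = b


def _windows_from_mismatches(mism: np.ndarray, lo: int, hi: int, m: int):
    """Maximal <=m-mismatch windows over domain [lo, hi] given sorted
    mismatch positions; yields (start, end_inclusive, n_mismatches).

    When more than m mismatches exist, every maximal window is bounded by
    two entries of the sentinel-padded mismatch list that are m+1 apart and
    contains exactly the m mismatches between them.
    """
    if len(mism) <= m:
        yield lo, hi, len(mism)
        return
    bounds = np.concatenate(([lo - 1], mism, [hi + 1]))
    wl = bounds[: -(m + 1)]
    wr = bounds[m + 1 :]
    for left, right in zip(wl.tolist(), wr.tolist()):
        yield left + 1, right - 1, m


def _qualifying_windows(
    mism: np.ndarray, lo: int, hi: int, m: int, min_len: int, max_len: int | None
):
    """Vectorized filter of _windows_from_mismatches by window length."""
    if len(mism) <= m:
        L = hi - lo + 1
        if L >= min_len and (max_len is None or L <= max_len):
            return [(lo, hi, len(mism))]
        return []
    bounds = np.concatenate(([lo - 1], mism, [hi + 1]))
    wl = bounds[: -(m + 1)]
    wr = bounds[m + 1 :]
    L = wr - wl - 1
    mask = L >= min_len
    if max_len is not None:
        mask &= L <= max_len
    if not mask.any():
        return []
    return [(int(a) + 1, int(e) - 1, m) for a, e in zip(wl[mask], wr[mask])]


def brute_force_dispersed(
    seq: str, min_len: int = 30, max_mismatch: int = 3
) -> set[tuple]:
    """All maximal dispersed-repeat pairs as
    (category, start1, start2, length, mismatches) tuples."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    carr = _COMP_TBL[arr]
    out: set[tuple] = set()

    # diagonal geometries: pair (a, a+d)
    for d in range(1, n):
        x = arr[: n - d]
        for category, y in (("forward", arr[d:]), ("complement", carr[d:])):
            mism = np.flatnonzero(x != y)
            for a, e, mm in _qualifying_windows(
                mism, 0, n - d - 1, max_mismatch, min_len, d
            ):
                out.add((category, a, a + d, e - a + 1, mm))

    # anti-diagonal geometries: cells (u, s-u), u < s-u
    for s in range(1, 2 * n - 2):
        lo = max(0, s - n + 1)
        hi = (s - 1) // 2
        if hi - lo + 1 < min_len:
            continue
        u = np.arange(lo, hi + 1)
        x = arr[u]
        v = arr[s - u]
        for category, y in (("reverse", v), ("palindromic", _COMP_TBL[v])):
            mism = np.flatnonzero(x != y) + lo
            for a, e, mm in _qualifying_windows(
                mism, lo, hi, max_mismatch, min_len, None
            ):
                out.add((category, a, s - e, e - a + 1, mm))
    return out


def brute_force_ng86_codon_pair(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-enumeration (nd, sd) for one codon pair, written directly
    from the definition (stop-avoiding paths, equal weights)."""
    from plastomics.selection import CODON_TABLE, STOP_CODONS

    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0
    all_paths = []
    ok_paths = []
    for perm in itertools.permutations(diffs):
        cur = c1
        nd = sd = 0
        blocked = False
        for p in perm:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            if nxt in STOP_CODONS:
                blocked = True
            cur = nxt
        all_paths.append((nd, sd))
        if not blocked:
            ok_paths.append((nd, sd))
    paths = ok_paths or all_paths
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def brute_force_site_counts(codon: str) -> tuple[float, float]:
    """Independent re-derivation of per-codon (n, s) site counts."""
    from plastomics.selection import CODON_TABLE, STOP_CODONS

    s_total = 0.0
    for pos in range(3):
        alternatives = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        allowed = [c for c in alternatives if c not in STOP_CODONS]
        if allowed:
            syn = sum(1 for c in allowed if CODON_TABLE[c] == CODON_TABLE[codon])
            s_total += syn / len(allowed)
    return 3.0 - s_total, s_total
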