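"""Repeat detection: microsatellites (SSRs), dispersed / palindromic repeat
pairs, and tandem repeat arrays.

Dispersed repeats follow a mathematical contract rather than any particular
tool's internals: a reported pair is a maximal window on a (anti-)diagonal
of the self-comparison matrix containing at most ``max_mismatch`` mismatching
cells, at least ``min_len`` cells long, with the two copies disjoint.  The
four categories differ only in the geometry/predicate:

==========  ============  =====================================
category    geometry      cell predicate (u in copy1, v in copy2)
==========  ============  =====================================
forward     diagonal      seq[v] == seq[u]
complement  diagonal      seq[v] == comp(seq[u])
reverse     anti-diagonal seq[v] == seq[u]
palindromic anti-diagonal seq[v] == comp(seq[u])
==========  ============  =====================================

Scanning is linear in genome coordinates (the circular origin is treated as
a boundary, as the reference tools do).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .model import Interval, Plastome, interval_length, make_interval

log = logging.getLogger(__name__)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

DEFAULT_SSR_THRESHOLDS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

@dataclass
class SSRRecord:
    motif: str
    unit_len: int
    copies: int
    start: int
    end: int  # start + copies * unit_len, mod genome length
    region: str = ""

    @property
    def length(self) -> int:
        return self.copies * self.unit_len


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


def find_ssrs(
    plastome: Plastome,
    thresholds: dict[int, int] = DEFAULT_SSR_THRESHOLDS,
) -> list[SSRRecord]:
    """All maximal perfect tandem runs of a primitive 1-6 bp unit meeting
    the per-unit-size copy threshold.

    Runs are reported at their smallest primitive unit only; runs containing
    N are split at the N; partial trailing copies are truncated.  The scan is
    circular (a run may cross the origin) and on the forward strand only.
    """
    seq = plastome.seq
    n = len(seq)
    s = seq + seq if plastome.circular else seq
    limit = len(s)
    records: list[SSRRecord] = []
    for u, thr in sorted(thresholds.items()):
        min_len = u * thr
        i = 0
        while i < limit - u:
            if s[i] == "N":
                i += 1
                continue
            # a true run start cannot extend one base to the left
            if i > 0:
                prev, wrap_prev = s[i - 1], s[i + u - 1]
            elif plastome.circular:
                prev, wrap_prev = s[n - 1], s[u - 1]
            else:
                prev = None
            if prev is not None and prev == wrap_prev and prev != "N":
                i += 1
                continue
            j = i
            while j + u < limit and s[j + u] == s[j] and s[j + u] != "N":
                j += 1
                if j - i + u >= n:  # full circle cap
                    break
            run_len = (j - i) + u
            if run_len >= min_len and i < n:
                motif = s[i : i + u]
                if _is_primitive(motif):
                    copies = run_len // u
                    records.append(
                        SSRRecord(
                            motif=motif,
                            unit_len=u,
                            copies=copies,
                            start=i,
                            end=(i + copies * u) % n,
                        )
                    )
                i += run_len
            else:
                i += 1
    if plastome.partition is not None:
        for r in records:
            r.region = plastome.partition.region_of(r.start)
    records.sort(key=lambda r: (r.start, r.unit_len))
    return records


# ---------------------------------------------------------------------------
# Dispersed / palindromic repeats
# ---------------------------------------------------------------------------

@dataclass
class RepeatRecord:
    category: str  # forward | reverse | complement | palindromic | tandem
    pos1: Interval
    pos2: Optional[Interval]
    length: int
    mismatches: int = 0
    score: int = 0
    period: int = 0
    copies: int = 0
    consensus: str = ""
    is_ir: bool = False

    def sort_key(self) -> tuple:
        return (-self.length, self.pos1.start, self.pos2.start if self.pos2 else -1)


_GEOMETRIES = (
    ("forward", "diag", False),
    ("complement", "diag", True),
    ("reverse", "anti", False),
    ("palindromic", "anti", True),
)


def _seed_pairs(seq: str, k: int):
    """Index exact k-mers and yield, per geometry, a dict mapping the
    (anti-)diagonal id to the sorted cell starts of seed runs."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    def rc(s: str) -> str:
        return "".join(_COMP[c] for c in reversed(s))

    def comp(s: str) -> str:
        return "".join(_COMP[c] for c in s)

    out: dict[str, dict[int, set[int]]] = {g: {} for g, _, _ in _GEOMETRIES}

    def add_diag(cat: str, i: int, j: int) -> None:
        lo, hi = (i, j) if i <= j else (j, i)
        if lo != hi:
            out[cat].setdefault(hi - lo, set()).add(lo)

    def add_anti(cat: str, i: int, j: int) -> None:
        out[cat].setdefault(i + j + k - 1, set()).add(min(i, j))

    for kmer, positions in index.items():
        # forward: same kmer, diagonal d = j - i
        if len(positions) > 1:
            for a in range(len(positions)):
                for b in range(a + 1, len(positions)):
                    add_diag("forward", positions[a], positions[b])
        # complement partner (comp(kmer) == kmer only for all-N windows)
        ck = comp(kmer)
        if kmer < ck:
            for i in positions:
                for j in index.get(ck, ()):
                    add_diag("complement", i, j)
        # reverse partner: seq[j:j+k] == reverse(seq[i:i+k])
        rk = kmer[::-1]
        if kmer < rk:
            for i in positions:
                for j in index.get(rk, ()):
                    add_anti("reverse", i, j)
        elif kmer == rk:
            for a in range(len(positions)):
                for b in range(a, len(positions)):
                    add_anti("reverse", positions[a], positions[b])
        # palindromic partner: seq[j:j+k] == revcomp(seq[i:i+k])
        pk = rc(kmer)
        if kmer < pk:
            for i in positions:
                for j in index.get(pk, ()):
                    add_anti("palindromic", i, j)
        elif kmer == pk:
            for a in range(len(positions)):
                for b in range(a, len(positions)):
                    add_anti("palindromic", positions[a], positions[b])
    return out


def _maximal_windows(bounds: list[int], m: int):
    """Maximal <=m-mismatch windows from a sorted list of mismatch positions
    flanked by boundary sentinels.  Yields (left_bound, right_bound) open
    intervals: the window is [left_bound+1, right_bound-1]."""
    t_max = len(bounds) - (m + 1)
    for t in range(max(t_max, 0)):
        yield bounds[t], bounds[t + m + 1], t
    if t_max <= 0:
        yield bounds[0], bounds[-1], 0


def find_dispersed_repeats(
    plastome_or_seq,
    min_len: int = 30,
    max_mismatch: int = 3,
    max_out: int | None = 100,
    seed_len: int | None = None,
) -> list[RepeatRecord]:
    """Maximal repeat pairs in the four dispersed categories.

    Output is truncated to the ``max_out`` longest records across categories
    (ties broken by coordinates); pass ``max_out=None`` for everything.
    The pair of whole-IR copies shows up as one palindromic hit flagged
    ``is_ir`` when the input carries a partition.
    """
    plastome = plastome_or_seq if isinstance(plastome_or_seq, Plastome) else None
    seq = plastome.seq if plastome else str(plastome_or_seq)
    n = len(seq)
    if seed_len is None:
        # pigeonhole: a min_len window with max_mismatch errors contains an
        # exact run of ceil((min_len - max_mismatch) / (max_mismatch + 1))
        seed_len = max(4, (min_len - max_mismatch) // (max_mismatch + 1))
    k = seed_len
    if n < 2 * k:
        return []
    seeds = _seed_pairs(seq, k)
    results: dict[tuple, RepeatRecord] = {}

    for category, geometry, use_comp in _GEOMETRIES:
        per_diag = seeds[category]
        for d, cell_starts in per_diag.items():
            if geometry == "diag":
                dom_lo, dom_hi = 0, n - d - 1

                def match(t, _d=d):
                    a = seq[t + _d]
                    b = seq[t]
                    return a == (_COMP[b] if use_comp else b)

            else:
                s_const = d
                dom_lo = max(0, s_const - n + 1)
                dom_hi = (s_const - 1) // 2

                def match(t, _s=s_const):
                    a = seq[_s - t]
                    b = seq[t]
                    return a == (_COMP[b] if use_comp else b)

            if dom_hi - dom_lo + 1 < min_len:
                continue
            # merge seed cells into candidate exact runs
            starts = sorted(cell_starts)
            runs: list[tuple[int, int]] = []
            for o in starts:
                lo, hi = max(o, dom_lo), min(o + k - 1, dom_hi)
                if hi - lo + 1 < 1:
                    continue
                if runs and lo <= runs[-1][1] + 1:
                    runs[-1] = (runs[-1][0], max(runs[-1][1], hi))
                else:
                    runs.append((lo, hi))
            done_runs: set[tuple[int, int]] = set()
            for lo, hi in runs:
                # extend to the true maximal exact run
                while lo > dom_lo and match(lo - 1):
                    lo -= 1
                while hi < dom_hi and match(hi + 1):
                    hi += 1
                if (lo, hi) in done_runs:
                    continue
                done_runs.add((lo, hi))
                if hi - lo + 1 < k:
                    continue
                # collect max_mismatch+1 mismatches beyond the run each side
                left_b: list[int] = []
                t = lo - 1
                while t >= dom_lo and len(left_b) <= max_mismatch:
                    if not match(t):
                        left_b.append(t)
                    t -= 1
                if len(left_b) <= max_mismatch:
                    left_b.append(dom_lo - 1)
                left_b.reverse()
                right_b: list[int] = []
                t = hi + 1
                while t <= dom_hi and len(right_b) <= max_mismatch:
                    if not match(t):
                        right_b.append(t)
                    t += 1
                if len(right_b) <= max_mismatch:
                    right_b.append(dom_hi + 1)
                bounds = left_b + right_b
                for wl, wr, t0 in _maximal_windows(bounds, max_mismatch):
                    if not (wl < lo and wr > hi):
                        continue  # window must contain the whole exact run
                    a, e = wl + 1, wr - 1
                    L = e - a + 1
                    if L < min_len:
                        continue
                    if geometry == "diag":
                        if L > d:
                            continue  # copies would overlap
                        pos1 = make_interval(a, a + L, n)
                        pos2 = make_interval(a + d, a + d + L, n)
                    else:
                        pos1 = make_interval(a, a + L, n)
                        pos2 = make_interval(d - e, d - a + 1, n)
                    mm = sum(1 for b in bounds if a <= b <= e)
                    key = (category, pos1.start, pos2.start, L)
                    results[key] = RepeatRecord(
                        category=category,
                        pos1=pos1,
                        pos2=pos2,
                        length=L,
                        mismatches=mm,
                    )

    records = sorted(results.values(), key=RepeatRecord.sort_key)
    if plastome is not None and plastome.partition is not None:
        part = plastome.partition
        ir_len = interval_length(part.irb, n)
        for r in records:
            if r.category == "palindromic" and r.length >= 0.95 * ir_len:
                c1 = {r.pos1.start, r.pos2.start}
                if any(abs(s - part.irb.start) <= ir_len * 0.05 for s in c1) and any(
                    abs(s - part.ira.start) <= ir_len * 0.05 for s in c1
                ):
                    r.is_ir = True
    if max_out is not None:
        records = records[:max_out]
    return records


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def _consensus(seq: str, a: int, b: int, period: int) -> str:
    """Majority-rule consensus of the period-sized columns of seq[a:b]."""
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for i in range(a, b):
        c = seq[i]
        col = cols[(i - a) % period]
        col[c] = col.get(c, 0) + 1
    out = []
    for col in cols:
        if not col:
            out.append("N")
        else:
            out.append(max(sorted(col), key=lambda c: col[c]))
    return "".join(out)


def _align_score(array: str, consensus_tiled: str, match: int, mismatch: int, indel: int) -> int:
    """Global alignment score of the array against its tiled consensus
    (+match per match, -mismatch per mismatch, -indel per gap position)."""
    if array == consensus_tiled:
        return match * len(array)
    la, lc = len(array), len(consensus_tiled)
    if la * lc > 600 * 600:
        # large array: gap-free column score is a faithful lower bound
        m = min(la, lc)
        sc = sum(
            (match if array[i] == consensus_tiled[i] else -mismatch) for i in range(m)
        )
        return sc - indel * abs(la - lc)
    prev = [-indel * j for j in range(lc + 1)]
    for i in range(1, la + 1):
        cur = [-indel * i] + [0] * lc
        ai = array[i - 1]
        for j in range(1, lc + 1):
            diag = prev[j - 1] + (match if ai == consensus_tiled[j - 1] else -mismatch)
            cur[j] = max(diag, prev[j] - indel, cur[j - 1] - indel)
        prev = cur
    return prev[lc]


def find_tandem_repeats(
    plastome_or_seq,
    match: int = 2,
    mismatch: int = 7,
    indel: int = 7,
    min_score: int = 80,
    max_period: int = 500,
    seed_len: int = 7,
) -> list[RepeatRecord]:
    """Tandem repeat arrays scored against their majority-rule consensus.

    Candidate periods come from recurring k-mer spacings.  Array boundaries
    are chosen to maximize the +match/-mismatch column score (which trims
    accidental flank extension), then the array is aligned globally against
    its tiled consensus.  Overlapping reports of one array at period
    multiples collapse to the highest-scoring period.
    """
    plastome = plastome_or_seq if isinstance(plastome_or_seq, Plastome) else None
    seq = plastome.seq if plastome else str(plastome_or_seq)
    n = len(seq)
    k = seed_len
    last_pos: dict[str, int] = {}
    candidates: set[tuple[int, int]] = set()  # (anchor, period)
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if kmer in last_pos:
            d = i - last_pos[kmer]
            if 1 <= d <= max_period:
                candidates.add((last_pos[kmer], d))
        last_pos[kmer] = i

    explored: dict[int, list[tuple[int, int]]] = {}
    accepted: list[RepeatRecord] = []
    for anchor, d in sorted(candidates, key=lambda t: (t[1], t[0])):
        inside = False
        for a, b in explored.get(d, ()):  # already swept this array at this period
            if a <= anchor < b:
                inside = True
                break
        if inside:
            continue
        # grow a region where period-d self-similarity holds
        lo = anchor
        fails = 0
        t = anchor - 1
        while t >= 0 and fails < 3:
            if t + d < n and seq[t] == seq[t + d]:
                lo = t
                fails = 0
            else:
                fails += 1
            t -= 1
        hi = anchor
        fails = 0
        t = anchor + 1
        while t + d < n and fails < 3:
            if seq[t] == seq[t + d]:
                hi = t
                fails = 0
            else:
                fails += 1
            t += 1
        a0, b0 = lo, min(hi + d + 1, n)
        explored.setdefault(d, []).append((a0, b0))
        if b0 - a0 < 2 * d:
            continue
        cons = _consensus(seq, a0, b0, d)
        # score-optimal trimming (best-sum contiguous subarray)
        best, best_a, best_b = 0, a0, a0
        cur, cur_a = 0, a0
        for i in range(a0, b0):
            v = match if seq[i] == cons[(i - a0) % d] else -mismatch
            cur += v
            if cur <= 0:
                cur, cur_a = 0, i + 1
            elif cur > best:
                best, best_a, best_b = cur, cur_a, i + 1
        if best_b - best_a < 2 * d:
            continue
        a1, b1 = best_a, best_b
        cons = _consensus(seq, a1, b1, d)
        copies = round((b1 - a1) / d)
        if copies < 2:
            continue
        tiled = (cons * (copies + 1))[: b1 - a1]
        score = _align_score(seq[a1:b1], tiled, match, mismatch, indel)
        if score < min_score:
            continue
        rec = RepeatRecord(
            category="tandem",
            pos1=make_interval(a1, b1, n),
            pos2=None,
            length=b1 - a1,
            score=score,
            period=d,
            copies=copies,
            consensus=cons,
        )
        # collapse period multiples / duplicate spans
        keep = True
        for idx, other in enumerate(accepted):
            oa, ob = other.pos1.start, other.pos1.start + other.length
            overlap = min(b1, ob) - max(a1, oa)
            if overlap <= 0:
                continue
            if overlap >= 0.8 * min(b1 - a1, other.length) and (
                d % other.period == 0 or other.period % d == 0 or d == other.period
            ):
                if (score, -d) > (other.score, -other.period):
                    accepted[idx] = rec
                keep = False
                break
        if keep:
            accepted.append(rec)
    accepted.sort(key=lambda r: r.pos1.start)
    return accepted


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_repeats(
    genome_id: str,
    ssrs: list[SSRRecord],
    dispersed: list[RepeatRecord],
    tandems: list[RepeatRecord],
) -> dict:
    """Per-genome counts in the shape of a repeat-distribution table row,
    plus SSR breakdowns by unit length and motif."""
    by_cat = {c: 0 for c in ("forward", "reverse", "complement", "palindromic")}
    for r in dispersed:
        by_cat[r.category] += 1
    ssr_by_unit = {u: 0 for u in range(1, 7)}
    ssr_by_motif: dict[str, int] = {}
    for s in ssrs:
        ssr_by_unit[s.unit_len] += 1
        ssr_by_motif[s.motif] = ssr_by_motif.get(s.motif, 0) + 1
    dispersed_subtotal = by_cat["forward"] + by_cat["reverse"] + by_cat["complement"]
    return {
        "genome": genome_id,
        "forward": by_cat["forward"],
        "reverse": by_cat["reverse"],
        "complement": by_cat["complement"],
        "dispersed_total": dispersed_subtotal,
        "palindromic": by_cat["palindromic"],
        "tandem": len(tandems),
        "total": dispersed_subtotal + by_cat["palindromic"] + len(tandems),
        "n_ssrs": len(ssrs),
        "ssr_by_unit": ssr_by_unit,
        "ssr_by_motif": ssr_by_motif,
    }
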