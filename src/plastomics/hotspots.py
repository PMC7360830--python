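"""Homologous-region extraction, alignment, and the variable-site
percentage used to rank mutational hotspots.

The variability statistic for one aligned region is

    percent = 100 * (S + I) / (L_aln - L_indel + I)

with S the number of substitution columns (non-gap columns showing >= 2
distinct unambiguous bases), I the number of indel events (maximal runs of
gap-containing columns, one event per run), L_aln the alignment length and
L_indel the number of gap-containing columns.  Columns holding both gaps
and substitutions count only on the indel side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import Plastome, interval_length

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Unaligned homologous sequences for one named region."""

    name: str
    rtype: str  # coding | noncoding
    taxa: list[str]
    seqs: list[str]
    flags: list[str] = field(default_factory=list)


def _coding_regions(plastome: Plastome) -> dict[str, str]:
    """One sequence per unique gene name, strand-normalized.

    IR-duplicated genes contribute the IRb-majority copy; same-name
    location blocks elsewhere (trans-spliced genes) are concatenated in
    genomic block order.
    """
    from .structure import _majority_region

    groups: dict[str, list] = {}
    for f in plastome.features:
        groups.setdefault(f.name, []).append(f)
    out = {}
    for name, feats in groups.items():
        if len(feats) == 1:
            out[name] = plastome.feature_seq(feats[0])
            continue
        if plastome.partition is not None:
            by_region = {_majority_region(f, plastome): f for f in feats}
            if "IRb" in by_region and "IRa" in by_region:
                out[name] = plastome.feature_seq(by_region["IRb"])
                continue
        out[name] = "".join(plastome.feature_seq(f) for f in feats)
    return out


def _spacer_regions(plastome: Plastome) -> dict[str, str]:
    """Intergenic spacers named by their ordered flanking gene pair."""
    n = len(plastome.seq)
    feats = sorted(plastome.features, key=lambda f: f.span(n).start)
    out = {}
    for a, b in zip(feats, feats[1:] + feats[:1]):
        sa = a.span(n)
        sb = b.span(n)
        end_a = sa.start + interval_length(sa, n)
        start_b = sb.start if b is not feats[0] else sb.start + n
        gap = start_b - end_a
        if gap <= 0:
            continue
        name = f"{a.name}-{b.name}"
        start = end_a % n
        stop = (end_a + gap) % n
        out[name] = (
            plastome.seq[start:stop]
            if start < stop
            else plastome.seq[start:] + plastome.seq[:stop]
        )
    return out


def extract_shared_regions(plastomes: list[Plastome]) -> dict[str, RegionSet]:
    """Regions (genes and spacers) present in every genome, keyed by name.

    Spacers require the same ordered flanking gene pair in every genome;
    regions empty in any genome are dropped with a logged reason.
    """
    if len(plastomes) < 2:
        raise ValueError("need at least 2 annotated genomes")
    taxa = [p.id for p in plastomes]
    coding = [_coding_regions(p) for p in plastomes]
    spacers = [_spacer_regions(p) for p in plastomes]
    out: dict[str, RegionSet] = {}
    for rtype, maps in (("coding", coding), ("noncoding", spacers)):
        shared = set(maps[0])
        for m in maps[1:]:
            shared &= set(m)
        dropped = set(maps[0]) - shared
        if dropped:
            log.info("dropping %d %s regions absent from some genome", len(dropped), rtype)
        for name in sorted(shared):
            seqs = [m[name] for m in maps]
            if any(not s for s in seqs):
                log.info("dropping region %s: zero length in some genome", name)
                continue
            out[name] = RegionSet(name=name, rtype=rtype, taxa=list(taxa), seqs=seqs)
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class RegionAlignment:
    name: str
    rtype: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0])


_NEG = -(10 ** 7)


def pairwise_align(
    s1: str,
    s2: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> tuple[str, str, int]:
    """Global affine-gap alignment (Gotoh); returns gapped s1, gapped s2,
    and the alignment score.  The inner recursion is vectorized per row."""
    n, m = len(s1), len(s2)
    if n == 0 or m == 0:
        raise ValueError("cannot align an empty sequence")
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    jar = np.arange(m + 1)
    shape = (n + 1, m + 1)
    M = np.empty(shape, dtype=np.int32)
    X = np.empty(shape, dtype=np.int32)  # gap in s2 (consume s1)
    Y = np.empty(shape, dtype=np.int32)  # gap in s1 (consume s2)
    M.fill(_NEG)
    X.fill(_NEG)
    Y.fill(_NEG)
    M[0, 0] = 0
    Y[0, 1:] = gap_open + gap_extend * (jar[1:] - 1)
    ext_ramp = gap_extend * jar
    y_tail = gap_open + gap_extend * (jar[1:] - 1)
    for i in range(1, n + 1):
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Xi = np.maximum(Mp + gap_open, Xp + gap_extend, out=X[i])
        best_prev = np.maximum(np.maximum(Mp, Xp), Yp)
        sub = np.where(a2 == a1[i - 1], match, mismatch)
        M[i, 1:] = best_prev[:-1] + sub
        # Y[i,j] = max_k<j ( M[i,k] + gap_open + gap_extend*(j-1-k) )
        run = np.maximum.accumulate(M[i] - ext_ramp)
        Y[i, 1:] = run[:-1] + y_tail
    # traceback, preferring M > X > Y on ties
    i, j = n, m
    states = [M[n, m], X[n, m], Y[n, m]]
    state = int(np.argmax(states))
    score = int(states[state])
    o1: list[str] = []
    o2: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            o1.append(s1[i - 1])
            o2.append(s2[j - 1])
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            target = M[i, j] - sub
            i, j = i - 1, j - 1
            opts = (M[i, j], X[i, j], Y[i, j])
            state = next(t for t in range(3) if opts[t] == target)
        elif state == 1:  # X: gap in s2
            o1.append(s1[i - 1])
            o2.append("-")
            if i - 1 >= 0 and X[i, j] == M[i - 1, j] + gap_open:
                state = 0
            i -= 1
        else:  # Y: gap in s1
            o1.append("-")
            o2.append(s2[j - 1])
            if Y[i, j] == M[i, j - 1] + gap_open:
                state = 0
            j -= 1
    return "".join(reversed(o1)), "".join(reversed(o2)), score


def _kmer_sim(s1: str, s2: str, k: int = 8) -> float:
    if len(s1) < k or len(s2) < k:
        return 1.0 if s1 == s2 else 0.0
    k1 = {s1[i : i + k] for i in range(len(s1) - k + 1)}
    k2 = {s2[i : i + k] for i in range(len(s2) - k + 1)}
    inter = len(k1 & k2)
    union = len(k1 | k2)
    return inter / union if union else 0.0


def _msa_consensus(rows: list[str]) -> str:
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=lambda c: counts[c]) if counts else "N")
    return "".join(out)


def align_region(
    region: RegionSet,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> RegionAlignment:
    """Progressive global alignment: center-star guide order by k-mer
    similarity, then successive profile merges against the running
    majority consensus.  Deterministic for fixed inputs."""
    seqs = region.seqs
    if any(not s for s in seqs):
        raise ValueError(f"region {region.name}: empty sequence among inputs")
    if len(seqs) == 1:
        raise ValueError("need >= 2 sequences")
    nseq = len(seqs)
    sims = [[0.0] * nseq for _ in range(nseq)]
    for i in range(nseq):
        for j in range(i + 1, nseq):
            sims[i][j] = sims[j][i] = _kmer_sim(seqs[i], seqs[j])
    center = max(range(nseq), key=lambda i: (sum(sims[i]), -i))
    order = [center] + sorted(
        (i for i in range(nseq) if i != center), key=lambda i: (-sims[center][i], i)
    )
    rows = [seqs[order[0]]]
    for idx in order[1:]:
        cons = _msa_consensus(rows)
        g_cons, g_new, _ = pairwise_align(cons, seqs[idx], match, mismatch, gap_open, gap_extend)
        new_rows = [[] for _ in range(len(rows) + 1)]
        col = 0
        for cc, nc in zip(g_cons, g_new):
            if cc == "-":
                for r in range(len(rows)):
                    new_rows[r].append("-")
            else:
                for r in range(len(rows)):
                    new_rows[r].append(rows[r][col])
                col += 1
            new_rows[-1].append(nc)
        rows = ["".join(r) for r in new_rows]
    # restore input taxon order
    unorder = [0] * nseq
    for rank, idx in enumerate(order):
        unorder[idx] = rank
    rows = [rows[unorder[i]] for i in range(nseq)]
    return RegionAlignment(region.name, region.rtype, list(region.taxa), rows)


def import_alignment(name: str, rtype: str, records: list[tuple[str, str]]) -> RegionAlignment:
    """Accept a pre-computed aligned FASTA verbatim (row lengths must match)."""
    taxa = [t for t, _ in records]
    rows = [s for _, s in records]
    return RegionAlignment(name, rtype, taxa, rows)


# ---------------------------------------------------------------------------
# Variability statistic
# ---------------------------------------------------------------------------

@dataclass
class VariabilityResult:
    name: str
    rtype: str
    S: int
    I: int
    L_aln: int
    L_indel: int
    percent: float
    undefined: bool = False


def variability_percent(aln: RegionAlignment) -> VariabilityResult:
    """The variable-site percentage with its four components.

    A gap column is any column where some row holds '-'; indel events are
    maximal runs of gap columns; substitution columns are non-gap columns
    with >= 2 distinct bases among non-N residues.
    """
    rows = aln.rows
    L = len(rows[0])
    S = 0
    L_indel = 0
    I = 0
    in_gap_run = False
    for col in zip(*rows):
        if "-" in col:
            L_indel += 1
            if not in_gap_run:
                I += 1
                in_gap_run = True
            continue
        in_gap_run = False
        bases = {c for c in col if c != "N"}
        if len(bases) >= 2:
            S += 1
    denom = L - L_indel + I
    if denom > 0:
        percent = 100.0 * (S + I) / denom
        undefined = False
    else:
        percent = 0.0
        undefined = True
    return VariabilityResult(
        name=aln.name,
        rtype=aln.rtype,
        S=S,
        I=I,
        L_aln=L,
        L_indel=L_indel,
        percent=percent,
        undefined=undefined,
    )


def rank_hotspots(
    results: list[VariabilityResult], k: int = 7, threshold: float = 0.5
) -> list[tuple[VariabilityResult, bool]]:
    """Top-k regions by percent (ties by larger aligned length, then name),
    each flagged when percent exceeds the threshold."""
    if not results:
        return []
    ranked = sorted(results, key=lambda r: (-r.percent, -r.L_aln, r.name))
    return [(r, r.percent > threshold) for r in ranked[:k]]


def combine_hotspot_sets(
    genus_topk: list[str], family_topk: list[str]
) -> dict[str, object]:
    """Intersection and union of two named hotspot lists."""
    g, f = set(genus_topk), set(family_topk)
    inter = sorted(g & f)
    union = sorted(g | f)
    return {
        "intersection": inter,
        "union": union,
        "n_intersection": len(inter),
        "n_union": len(union),
    }
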