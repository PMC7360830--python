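"""Quadripartite structure: inverted-repeat detection, LSC/IRb/SSC/IRa
partitioning, per-region GC content, junction gene contexts, and the gene
inventory."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import (
    GeneFeature,
    Interval,
    Plastome,
    QuadripartitePartition,
    interval_length,
    make_interval,
)

log = logging.getLogger(__name__)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


class PartitionError(ValueError):
    """Genome has no qualifying inverted-repeat pair (non-quadripartite)."""


def _circular_kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    n = len(seq)
    ext = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(ext[i : i + k], []).append(i)
    return index


def detect_ir(
    plastome: Plastome, min_ir_len: int = 1000, max_mismatch: int = 0
) -> QuadripartitePartition:
    """Find the maximal pair of disjoint reverse-complement segments and
    partition the circle into LSC / IRb / SSC / IRa.

    Copies are extended maximally on both flanks; with the default
    ``max_mismatch=0`` extension stops at the first non-complementary base
    pair, so junction placement is bit-exact.  Ties between equal-length
    candidate pairs are broken by smaller start coordinate.  IRb is the IR
    copy immediately downstream of the LSC in input orientation.
    """
    seq = plastome.seq
    n = len(seq)
    if n < 2 * min_ir_len:
        raise PartitionError(f"{plastome.id}: genome too short for IRs >= {min_ir_len} bp")
    k = min(20, min_ir_len)
    index = _circular_kmer_index(seq, k)
    ext = seq + seq[: k - 1]

    # anti-diagonal constant: position u in copy1 pairs with v = (c - u) mod n
    covered: dict[int, list[tuple[int, int]]] = {}
    candidates: list[tuple[int, int, int]] = []  # (L, lo, c)

    from .model import revcomp as _rc

    for i in range(n):
        kmer = ext[i : i + k]
        rc = _rc(kmer)
        if rc not in index:
            continue
        for j in index[rc]:
            c = (i + j + k - 1) % n
            skip = False
            for a, b in covered.get(c, ()):  # position ranges already explained
                if a <= i <= b:
                    skip = True
                    break
            if skip:
                continue
            if (j - i) % n < k or (i - j) % n < k:
                continue  # seed copies overlap on the circle
            lo, hi = i, i + k - 1
            L = k
            # gaps between the two copies on the circle
            gap_left = (i - j - k) % n
            gap_right = (j - i - k) % n
            budget = max_mismatch
            # extend left flank of copy1 (= right flank of copy2)
            mm_l = 0
            while gap_left >= 2:
                u = (lo - 1) % n
                v = (c - u) % n
                if seq[v] == _COMP[seq[u]]:
                    mm_l = 0
                elif budget > 0:
                    budget -= 1
                    mm_l += 1
                else:
                    break
                lo -= 1
                L += 1
                gap_left -= 2
            lo += mm_l  # never end on a mismatch
            L -= mm_l
            mm_r = 0
            while gap_right >= 2:
                u = (hi + 1) % n
                v = (c - u) % n
                if seq[v] == _COMP[seq[u]]:
                    mm_r = 0
                elif budget > 0:
                    budget -= 1
                    mm_r += 1
                else:
                    break
                hi += 1
                L += 1
                gap_right -= 2
            hi -= mm_r
            L -= mm_r
            lo_mod = lo % n
            copy2_lo = (c - hi) % n
            covered.setdefault(c, []).append(((lo_mod), (lo_mod + L - 1)))
            covered.setdefault(c, []).append((copy2_lo, copy2_lo + L - 1))
            if L >= min_ir_len and 2 * L < n:
                candidates.append((L, lo_mod, c))

    if not candidates:
        raise PartitionError(
            f"{plastome.id}: no inverted repeat pair >= {min_ir_len} bp found"
        )
    candidates.sort(key=lambda t: (-t[0], t[1]))
    L, lo, c = candidates[0]
    hi = lo + L - 1
    copy1 = make_interval(lo, lo + L, n)
    copy2 = make_interval(c - hi, c - hi + L, n)
    # single-copy gaps: after copy1 up to copy2, and after copy2 up to copy1
    gap1 = make_interval(lo + L, c - hi, n)
    gap2 = make_interval(c - lo + 1, lo, n)
    len1 = interval_length(gap1, n)
    len2 = interval_length(gap2, n)
    if len1 == 0 or len2 == 0:
        raise PartitionError(f"{plastome.id}: IR copies are adjacent, no single-copy regions")
    if len1 >= len2:
        lsc, ssc = gap1, gap2
        irb, ira = copy2, copy1  # copy2 starts where gap1 (LSC) ends
    else:
        lsc, ssc = gap2, gap1
        irb, ira = copy1, copy2
    part = QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n)
    part.validate()
    return part


def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases; N excluded from numerator and
    denominator.  Raises ValueError on an effectively all-N sequence."""
    if not seq:
        raise ValueError("empty sequence")
    g = seq.count("G") + seq.count("C")
    atgc = g + seq.count("A") + seq.count("T")
    if atgc == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * g / atgc


@dataclass
class JunctionContext:
    """Gene context at one single-copy / inverted-repeat junction."""

    junction: str
    junction_pos: int
    overlapping_genes: list[tuple[str, int, int]] = field(default_factory=list)
    nearest_gene_left: tuple[str, int] | None = None
    nearest_gene_right: tuple[str, int] | None = None


_JUNCTIONS = (
    ("LSC/IRb", "lsc", "irb"),
    ("IRb/SSC", "irb", "ssc"),
    ("SSC/IRa", "ssc", "ira"),
    ("IRa/LSC", "ira", "lsc"),
)


def junction_report(plastome: Plastome) -> list[JunctionContext]:
    """For each of the four junctions, report genes straddling it (with bp
    on each side) and the nearest gene on either side."""
    part = plastome.partition
    if part is None:
        raise ValueError("plastome has no partition; run detect_ir first")
    n = len(plastome.seq)
    out = []
    for name, _up, down in _JUNCTIONS:
        p = getattr(part, down).start
        ctx = JunctionContext(junction=name, junction_pos=p)
        best_left: tuple[int, str] | None = None
        best_right: tuple[int, str] | None = None
        for f in plastome.features:
            span = f.span(n)
            span_len = interval_length(span, n)
            if span.contains(p, n) and span.contains((p - 1) % n, n):
                left_bp = (p - span.start) % n
                right_bp = span_len - left_bp
                if 0 < left_bp and 0 < right_bp:
                    ctx.overlapping_genes.append((f.name, left_bp, right_bp))
                    continue
            gap_left = (p - span.end) % n
            gap_right = (span.start - p) % n
            if gap_left <= gap_right:
                if best_left is None or gap_left < best_left[0]:
                    best_left = (gap_left, f.name)
            else:
                if best_right is None or gap_right < best_right[0]:
                    best_right = (gap_right, f.name)
        if best_left:
            ctx.nearest_gene_left = (best_left[1], best_left[0])
        if best_right:
            ctx.nearest_gene_right = (best_right[1], best_right[0])
        out.append(ctx)
    return out


@dataclass
class GeneInventory:
    n_genes_unique: int
    n_protein_coding: int
    n_trna: int
    n_rrna: int
    n_other: int
    n_ir_duplicated: int
    duplicated_by_kind: dict[str, int]
    genes_with_introns: list[tuple[str, int]]


def _majority_region(feat: GeneFeature, plastome: Plastome) -> str:
    """Region holding the majority of the feature's bases."""
    part = plastome.partition
    n = len(plastome.seq)
    counts = {r: 0 for r in ("LSC", "IRb", "SSC", "IRa")}
    for e in feat.exons:
        pos = e.start
        for _ in range(interval_length(e, n)):
            counts[part.region_of(pos % n)] += 1
            pos += 1
    return max(counts, key=lambda r: counts[r])


def gene_inventory(plastome: Plastome) -> GeneInventory:
    """Count unique genes by class, IR-duplicated genes, and introns.

    Same-name features with one copy (majority) in IRb and another in IRa
    are IR duplicates and count once.  Other same-name groups are treated
    as location blocks of one trans-spliced gene: the gene counts once and
    its intron count is (total exons across blocks) - 1; a warning is
    logged since this is a convention, not an annotation fact.
    """
    part = plastome.partition
    groups: dict[str, list[GeneFeature]] = {}
    for f in plastome.features:
        groups.setdefault(f.name, []).append(f)

    kinds = {"CDS": 0, "tRNA": 0, "rRNA": 0, "other": 0}
    dup_by_kind = {"CDS": 0, "tRNA": 0, "rRNA": 0, "other": 0}
    n_dup = 0
    introns: list[tuple[str, int]] = []
    for name, feats in sorted(groups.items()):
        kind = feats[0].kind
        kinds[kind] += 1
        is_dup = False
        if len(feats) >= 2 and part is not None:
            regions = {_majority_region(f, plastome) for f in feats}
            if {"IRb", "IRa"} <= regions:
                is_dup = True
        if is_dup:
            n_dup += 1
            dup_by_kind[kind] += 1
            n_introns = max(f.intron_count() for f in feats)
        elif len(feats) >= 2:
            log.warning(
                "gene %s has %d same-name features outside the IR pair; "
                "treating as blocks of one (trans-spliced) gene",
                name,
                len(feats),
            )
            n_introns = sum(len(f.exons) for f in feats) - 1
        else:
            n_introns = feats[0].intron_count()
        if n_introns > 0:
            introns.append((name, n_introns))

    return GeneInventory(
        n_genes_unique=len(groups),
        n_protein_coding=kinds["CDS"],
        n_trna=kinds["tRNA"],
        n_rrna=kinds["rRNA"],
        n_other=kinds["other"],
        n_ir_duplicated=n_dup,
        duplicated_by_kind=dup_by_kind,
        genes_with_introns=introns,
    )


def region_gc(plastome: Plastome) -> dict[str, float]:
    """GC content per region plus the whole genome."""
    part = plastome.partition
    if part is None:
        raise ValueError("plastome has no partition")
    out = {"genome": gc_content(plastome.seq)}
    for name, iv in part.regions().items():
        out[name] = gc_content(plastome.slice(iv))
    return out
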