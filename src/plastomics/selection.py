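"""Codon-aware dN/dS screen: Nei-Gojobori (1986) site/difference counting
with Jukes-Cantor correction, averaged over all pairwise comparisons per
gene.  Genetic code: translation table 11; stops {TAA, TAG, TGA}.

This is a deliberately simple counting screen (equal pathway weighting, no
site models); it flags genes with mean omega > 1 as candidates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .hotspots import RegionAlignment

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class InternalStopError(ValueError):
    pass


def translate(codon: str) -> str:
    return CODON_TABLE[codon]


def codon_partition(cds_seq: str) -> list[str]:
    """Split a CDS into codons, trimming one terminal stop codon.

    Raises on length not divisible by 3 or on an internal stop.
    """
    seq = cds_seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for pos, c in enumerate(codons):
        if c in STOP_CODONS:
            raise InternalStopError(f"internal stop codon {c} at codon {pos + 1}")
    return codons


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one codon.

    Per position, the synonymous fraction is computed over the non-stop
    single-nucleotide changes only; n_sites is 3 minus the synonymous
    total, so each position always contributes one full site.
    """
    if codon in STOP_CODONS:
        raise ValueError("site counts undefined for a stop codon")
    aa = CODON_TABLE[codon]
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            considered += 1
            if CODON_TABLE[mut] == aa:
                syn += 1
        if considered:
            s_sites += syn / considered
    return 3.0 - s_sites, s_sites


def ng86_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) difference counts for a
    codon pair: equal weight over orderings of the differing positions,
    excluding pathways that pass through a stop codon (unless all do)."""
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(diffs):
        cur = c1
        nd = sd = 0
        blocked = False
        for p in perm:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((nd, sd))
    if not paths:  # every pathway passes a stop; fall back to including them
        for perm in itertools.permutations(diffs):
            cur = c1
            nd = sd = 0
            for p in perm:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((nd, sd))
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


@dataclass
class DnDsResult:
    gene: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float  # nan when undefined
    saturated: bool = False

    @property
    def omega_defined(self) -> bool:
        return not math.isnan(self.omega)


def ng86_pairwise(cds1: str, cds2: str, gene: str = "") -> DnDsResult:
    """NG86 dN/dS for two codon-aligned CDSs.

    Codons containing gaps or N in either sequence are skipped; site counts
    are averaged over the two sequences; Jukes-Cantor correction is applied
    to the raw proportions.
    """
    codons1 = [cds1[i : i + 3] for i in range(0, len(cds1), 3)]
    codons2 = [cds2[i : i + 3] for i in range(0, len(cds2), 3)]
    if len(codons1) != len(codons2):
        raise ValueError("sequences differ in codon count")
    n1 = s1 = n2 = s2 = nd = sd = 0.0
    compared = 0
    ok = set("ACGT")
    for a, b in zip(codons1, codons2):
        if not (set(a) <= ok and set(b) <= ok):
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            continue
        compared += 1
        na, sa = ng86_site_counts(a)
        nb, sb = ng86_site_counts(b)
        n1 += na
        s1 += sa
        n2 += nb
        s2 += sb
        d_n, d_s = ng86_pair_differences(a, b)
        nd += d_n
        sd += d_s
    if compared == 0:
        raise ValueError(f"gene {gene or '?'}: no comparable codons")
    n_sites = (n1 + n2) / 2.0
    s_sites = (s1 + s2) / 2.0
    pN = nd / n_sites if n_sites > 0 else 0.0
    pS = sd / s_sites if s_sites > 0 else 0.0
    dN, satN = _jc_correct(pN)
    dS, satS = _jc_correct(pS)
    saturated = satN or satS
    if saturated or math.isnan(dS) or dS <= 0.0:
        omega = float("nan")
    else:
        omega = dN / dS
    return DnDsResult(
        gene=gene,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pN=pN,
        pS=pS,
        dN=dN,
        dS=dS,
        omega=omega,
        saturated=saturated,
    )


def selection_screen(gene_alignments: dict[str, RegionAlignment]) -> list[dict]:
    """Mean pairwise NG86 per gene across taxa; rows sorted by omega
    descending with genes of mean omega > 1 flagged."""
    rows = []
    for gene, aln in sorted(gene_alignments.items()):
        pair_results = []
        for i in range(len(aln.rows)):
            for j in range(i + 1, len(aln.rows)):
                try:
                    pair_results.append(ng86_pairwise(aln.rows[i], aln.rows[j], gene))
                except ValueError:
                    continue
        if not pair_results:
            continue
        def _mean(vals):
            vals = [v for v in vals if not math.isnan(v)]
            return sum(vals) / len(vals) if vals else float("nan")
        dN = _mean([r.dN for r in pair_results])
        dS = _mean([r.dS for r in pair_results])
        omegas = [r.omega for r in pair_results if not math.isnan(r.omega)]
        if omegas:
            omega = sum(omegas) / len(omegas)
        elif not math.isnan(dN) and dN > 0 and dS == 0:
            omega = float("inf")  # nonsynonymous change with zero synonymous rate
        else:
            omega = float("nan")
        rows.append(
            {
                "gene": gene,
                "n_pairs": len(pair_results),
                "dN": dN,
                "dS": dS,
                "omega": omega,
                "positive_selection_flag": (not math.isnan(omega)) and omega > 1.0,
                "saturated": any(r.saturated for r in pair_results),
            }
        )
    rows.sort(key=lambda r: (-(r["omega"] if not math.isnan(r["omega"]) else -1), r["gene"]))
    return rows
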