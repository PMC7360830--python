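"""Synthetic plastome generator: quadripartite ancestors with planted
genes, SSRs and repeats, evolved along a tree with region-specific
substitution multipliers and an indel process.

Conventions (documented simplifications):

* branch lengths are expected substitutions per site at multiplier 1;
* mutations are sampled once on IRb and mirrored onto IRa, keeping the two
  IR copies identical;
* indel events fall only in single-copy intergenic positions, so gene
  boundaries and reading frames survive and region extraction stays
  well-defined;
* planted repeat/SSR flanks are "sealed" (forced mismatches) so planted
  coordinates are exactly maximal.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .model import (
    GeneFeature,
    Interval,
    Plastome,
    QuadripartitePartition,
    make_interval,
    revcomp,
)
from .phylo import TreeNode, parse_newick

log = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class ConfigError(ValueError):
    pass


@dataclass
class GeneSpec:
    """A gene to plant: single- or multi-exon, optionally straddling the
    LSC/IRb junction (``junction_bp`` = bases inside IRb)."""

    name: str
    kind: str = "CDS"
    region: str = "LSC"
    length: int = 300
    n_exons: int = 1
    intron_length: int = 60
    strand: str = "+"
    junction_bp: int = 0  # >0: gene ends this many bp inside IRb


@dataclass
class SimulationConfig:
    genome_length: int = 156000
    ir_length: int = 25650
    ssc_length: int = 19000
    gc: float = 0.363
    genes: list[GeneSpec] = field(default_factory=list)
    planted_ssrs: list[tuple[str, int]] = field(default_factory=list)
    planted_dispersed: list[tuple[str, int]] = field(default_factory=list)  # (category, length)
    planted_tandems: list[tuple[str, int]] = field(default_factory=list)  # (motif, copies)
    mu: float = 1.0
    gene_multiplier: float = 0.3
    spacer_multipliers: dict[str, float] = field(default_factory=dict)
    default_spacer_multiplier: float = 1.0
    indel_rate: float = 0.0  # events per eligible site per branch-length unit
    indel_geom_p: float = 0.5
    indel_cap: int = 10
    tree: str = ""
    species_map: dict[str, str] = field(default_factory=dict)

    def lsc_length(self) -> int:
        lsc = self.genome_length - 2 * self.ir_length - self.ssc_length
        if lsc <= 0:
            raise ConfigError("genome too small for the requested IR/SSC lengths")
        if lsc < self.ssc_length:
            raise ConfigError("LSC must be at least as long as SSC")
        return lsc

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        data = json.loads(text)
        genes = [GeneSpec(**g) for g in data.pop("genes", [])]
        data["planted_ssrs"] = [tuple(x) for x in data.get("planted_ssrs", [])]
        data["planted_dispersed"] = [tuple(x) for x in data.get("planted_dispersed", [])]
        data["planted_tandems"] = [tuple(x) for x in data.get("planted_tandems", [])]
        return cls(genes=genes, **data)


@dataclass
class SyntheticTruth:
    tree: str
    multipliers: dict[str, float]
    multiplier_intervals: list[tuple[int, int, float]]
    planted_ssrs: list[dict]
    planted_dispersed: list[dict]
    planted_tandems: list[dict]
    gene_coords: dict[str, list[tuple[int, int]]]
    species_map: dict[str, str]
    partition_lengths: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def _random_cds(length: int, rng: np.random.Generator) -> str:
    """ATG + random non-stop codons + TAA, total ``length`` bases."""
    if length % 3 != 0 or length < 9:
        raise ConfigError("CDS length must be a multiple of 3 and >= 9")
    sense = [c for c in ("".join(b) for b in itertools.product("ACGT", repeat=3)) if c not in _STOPS]
    n_mid = length // 3 - 2
    mids = rng.integers(0, len(sense), n_mid)
    return "ATG" + "".join(sense[i] for i in mids) + "TAA"


def _differing_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


_COMP_STR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def build_ancestor(
    config: SimulationConfig, seed: int | np.random.Generator = 0
) -> tuple[Plastome, SyntheticTruth]:
    """Deterministically build the ancestral plastome plus its truth record."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.genome_length
    lsc_len = config.lsc_length()
    ir_len = config.ir_length
    ssc_len = config.ssc_length
    lsc = (0, lsc_len)
    irb = (lsc_len, lsc_len + ir_len)
    ssc = (irb[1], irb[1] + ssc_len)
    ira = (ssc[1], n)

    # background sequence at the target GC
    pg = config.gc / 2.0
    pa = (1.0 - config.gc) / 2.0
    seq = list(
        "".join(
            np.array(list("ACGT"))[
                rng.choice(4, size=n, p=[pa, pg, pg, pa])
            ]
        )
    )

    # --- plant genes ------------------------------------------------------
    by_region: dict[str, list[GeneSpec]] = {}
    straddlers: list[GeneSpec] = []
    for g in config.genes:
        if g.junction_bp > 0:
            straddlers.append(g)
        else:
            by_region.setdefault(g.region, []).append(g)

    features: list[GeneFeature] = []
    gene_coords: dict[str, list[tuple[int, int]]] = {}
    occupied: list[tuple[int, int]] = []  # gene spans, to keep plants apart

    def write_gene(g: GeneSpec, start: int) -> GeneFeature:
        span = g.length + (g.n_exons - 1) * g.intron_length
        if g.kind == "CDS" and g.n_exons == 1:
            content = _random_cds(g.length, rng)
        else:
            content = None  # keep background bases
        exons = []
        exon_len = g.length // g.n_exons
        pos = start
        written = 0
        for e in range(g.n_exons):
            el = exon_len if e < g.n_exons - 1 else g.length - exon_len * (g.n_exons - 1)
            if content is not None:
                seq[pos : pos + el] = list(content[written : written + el])
            written += el
            exons.append(make_interval(pos, pos + el, n))
            pos += el + g.intron_length
        feat = GeneFeature(g.name, g.kind, exons, g.strand)
        occupied.append((start, start + span))
        gene_coords.setdefault(g.name, []).append((start, start + span))
        return feat

    region_bounds = {"LSC": lsc, "IRb": irb, "SSC": ssc}
    margin = 60
    for region, genes in by_region.items():
        if region not in region_bounds:
            raise ConfigError(f"cannot place genes in region {region!r}")
        r0, r1 = region_bounds[region]
        spans = [g.length + (g.n_exons - 1) * g.intron_length for g in genes]
        free = (r1 - r0 - 2 * margin) - sum(spans)
        if free < len(genes) * 20:
            raise ConfigError(f"planted genes exceed space in {region}")
        gap = free // (len(genes) + 1)
        pos = r0 + margin + gap
        for g, span in zip(genes, spans):
            features.append(write_gene(g, pos))
            pos += span + gap
    for g in straddlers:
        # gene ends g.junction_bp inside IRb
        span = g.length + (g.n_exons - 1) * g.intron_length
        start = irb[0] + g.junction_bp - span
        if start <= lsc[0]:
            raise ConfigError("straddler does not fit in LSC")
        features.append(write_gene(g, start))

    # --- plant SSRs / repeats in free LSC+SSC space -----------------------
    def find_free(length: int) -> int:
        for _ in range(200):
            if rng.random() < 0.8:
                pos = int(rng.integers(lsc[0] + margin, lsc[1] - margin - length))
            else:
                pos = int(rng.integers(ssc[0] + margin, ssc[1] - margin - length))
            if all(pos + length + 2 <= s or pos >= e + 2 for s, e in occupied):
                occupied.append((pos - 1, pos + length + 1))
                return pos
        raise ConfigError("infeasible packing of planted features")

    planted_ssrs = []
    for motif, copies in config.planted_ssrs:
        u = len(motif)
        length = u * copies
        pos = find_free(length)
        seq[pos : pos + length] = list(motif * copies)
        # seal flanks so the run is exactly maximal
        seq[pos - 1] = _differing_base(rng, seq[pos + u - 1], "N")
        seq[pos + length] = _differing_base(rng, motif[0], "N")
        planted_ssrs.append(
            {"motif": motif, "unit_len": u, "copies": copies, "start": pos, "end": pos + length}
        )

    planted_dispersed = []
    for category, length in config.planted_dispersed:
        core = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, length)]
        )
        if category == "forward":
            second = core
        elif category == "reverse":
            second = core[::-1]
        elif category == "complement":
            second = "".join(_COMP_STR[c] for c in core)
        elif category == "palindromic":
            second = revcomp(core)
        else:
            raise ConfigError(f"unknown dispersed category {category!r}")
        p1 = find_free(length)
        p2 = find_free(length)
        if p1 > p2:
            p1, p2 = p2, p1
            if category in ("forward", "complement"):
                pass  # symmetric relations
        seq[p1 : p1 + length] = list(core)
        seq[p2 : p2 + length] = list(second)
        # seal both flank pairings for this category's geometry
        if category in ("forward", "complement"):
            tr = (lambda c: c) if category == "forward" else (lambda c: _COMP_STR[c])
            seq[p2 - 1] = _differing_base(rng, tr(seq[p1 - 1]), "N")
            seq[p2 + length] = _differing_base(rng, tr(seq[p1 + length]), "N")
        else:
            tr = (lambda c: c) if category == "reverse" else (lambda c: _COMP_STR[c])
            seq[p2 + length] = _differing_base(rng, tr(seq[p1 - 1]), "N")
            seq[p2 - 1] = _differing_base(rng, tr(seq[p1 + length]), "N")
        planted_dispersed.append(
            {"category": category, "length": length, "start1": p1, "start2": p2}
        )

    planted_tandems = []
    for motif, copies in config.planted_tandems:
        d = len(motif)
        length = d * copies
        pos = find_free(length)
        seq[pos : pos + length] = list(motif * copies)
        seq[pos - 1] = _differing_base(rng, motif[d - 1], "N")
        seq[pos + length] = _differing_base(rng, motif[0], "N")
        planted_tandems.append(
            {"motif": motif, "period": d, "copies": copies, "start": pos, "end": pos + length}
        )

    # --- mirror IRa from IRb, add IR gene copies --------------------------
    irb_seq = "".join(seq[irb[0] : irb[1]])
    seq[ira[0] : ira[1]] = list(revcomp(irb_seq))
    for f in list(features):
        inside = all(
            irb[0] <= e.start and e.end <= irb[1] for e in f.exons if not e.wrap
        ) and all(not e.wrap for e in f.exons)
        if inside and f.exons[0].start >= irb[0]:
            mirrored = []
            for e in reversed(f.exons):
                off_end = e.end - irb[0]
                off_start = e.start - irb[0]
                ms = ira[1] - off_end
                me = ira[1] - off_start
                mirrored.append(make_interval(ms, me, n))
            strand = "-" if f.strand == "+" else "+"
            features.append(GeneFeature(f.name, f.kind, mirrored, strand))
            gene_coords.setdefault(f.name, []).append(
                (mirrored[0].start, mirrored[-1].end)
            )

    # --- seal the IR junctions so detection is bit-exact ------------------
    if seq[0] == _COMP_STR[seq[irb[0] - 1]]:
        seq[0] = _differing_base(rng, _COMP_STR[seq[irb[0] - 1]], "N")
    if seq[ira[0] - 1] == _COMP_STR[seq[irb[1] % n]]:
        seq[ira[0] - 1] = _differing_base(rng, _COMP_STR[seq[irb[1] % n]], "N")

    partition = QuadripartitePartition(
        lsc=make_interval(*lsc, n),
        irb=make_interval(*irb, n),
        ssc=make_interval(*ssc, n),
        ira=make_interval(ira[0], 0, n),
        genome_length=n,
    )
    plastome = Plastome(
        id="ancestor", seq="".join(seq), features=features, partition=partition
    )

    # --- per-position multiplier intervals --------------------------------
    mult_intervals, mult_by_name = _multiplier_intervals(plastome, config)
    truth = SyntheticTruth(
        tree=config.tree,
        multipliers=mult_by_name,
        multiplier_intervals=mult_intervals,
        planted_ssrs=planted_ssrs,
        planted_dispersed=planted_dispersed,
        planted_tandems=planted_tandems,
        gene_coords=gene_coords,
        species_map=dict(config.species_map),
        partition_lengths=partition.lengths(),
    )
    return plastome, truth


def spacer_names(plastome: Plastome) -> list[tuple[str, int, int]]:
    """Ordered (name, start, end) for the spacers between annotated genes."""
    n = len(plastome.seq)
    feats = sorted(plastome.features, key=lambda f: f.span(n).start)
    out = []
    for a, b in zip(feats, feats[1:] + feats[:1]):
        sa, sb = a.span(n), b.span(n)
        end_a = sa.start + (sa.end - sa.start if not sa.wrap else n - sa.start + sa.end)
        start_b = sb.start if b is not feats[0] else sb.start + n
        if start_b - end_a > 0:
            out.append((f"{a.name}-{b.name}", end_a % n, start_b % n))
    return out


def _multiplier_intervals(
    plastome: Plastome, config: SimulationConfig
) -> tuple[list[tuple[int, int, float]], dict[str, float]]:
    n = len(plastome.seq)
    intervals: list[tuple[int, int, float]] = []
    by_name: dict[str, float] = {}
    for f in plastome.features:
        for e in f.exons:
            intervals.append((e.start, e.end if e.end > e.start else n, config.gene_multiplier))
        by_name.setdefault(f.name, config.gene_multiplier)
    for name, start, end in spacer_names(plastome):
        m = config.spacer_multipliers.get(name, config.default_spacer_multiplier)
        intervals.append((start, end if end > start else n, m))
        by_name[name] = m
    return intervals, by_name


# ---------------------------------------------------------------------------
# Evolution along a tree
# ---------------------------------------------------------------------------

@dataclass
class _State:
    seq: np.ndarray  # uint8 codes 0..3
    region: np.ndarray  # int8: 0 LSC, 1 IRb, 2 SSC, 3 IRa
    in_gene: np.ndarray  # bool
    mult: np.ndarray  # float
    features: list  # [name, kind, strand, [[s, e], ...]]

    def copy(self) -> "_State":
        return _State(
            self.seq.copy(),
            self.region.copy(),
            self.in_gene.copy(),
            self.mult.copy(),
            [[f[0], f[1], f[2], [list(e) for e in f[3]]] for f in self.features],
        )


def _state_from_plastome(plastome: Plastome, truth: SyntheticTruth) -> _State:
    n = len(plastome.seq)
    seq = np.frombuffer(plastome.seq.encode(), dtype=np.uint8).copy()
    codes = np.zeros(256, dtype=np.uint8)
    for b, c in _CODE.items():
        codes[ord(b)] = c
    seq = codes[seq]
    region = np.zeros(n, dtype=np.int8)
    part = plastome.partition
    for code, name in enumerate(("LSC", "IRb", "SSC", "IRa")):
        iv = part.regions()[name]
        if iv.wrap:
            region[iv.start :] = code
            region[: iv.end] = code
        else:
            region[iv.start : iv.end] = code
    in_gene = np.zeros(n, dtype=bool)
    feats = []
    for f in plastome.features:
        exons = []
        for e in f.exons:
            if e.wrap:
                in_gene[e.start :] = True
                in_gene[: e.end] = True
                exons.append([e.start, e.end + n])  # simulator forbids these anyway
            else:
                in_gene[e.start : e.end] = True
                exons.append([e.start, e.end])
        feats.append([f.name, f.kind, f.strand, exons])
    mult = np.ones(n, dtype=np.float64)
    for s, e, m in truth.multiplier_intervals:
        mult[s:e] = m
    return _State(seq, region, in_gene, mult, feats)


def _apply_branch(
    state: _State, t: float, config: SimulationConfig, rng: np.random.Generator
) -> _State:
    st = state.copy()
    n = len(st.seq)
    if t > 0:
        p = np.clip(config.mu * t * st.mult, 0.0, 0.95)
        hit = (rng.random(n) < p) & (st.region != 3)
        idx = np.flatnonzero(hit)
        if idx.size:
            st.seq[idx] = (st.seq[idx] + 1 + rng.integers(0, 3, idx.size).astype(np.uint8)) % 4
        # indels in single-copy intergenic space only
        if config.indel_rate > 0:
            eligible = ((st.region == 0) | (st.region == 2)) & ~st.in_gene
            lam = config.indel_rate * t * int(eligible.sum())
            for _ in range(rng.poisson(lam)):
                length = min(int(rng.geometric(config.indel_geom_p)), config.indel_cap)
                is_del = rng.random() < 0.5
                pos = -1
                elig_idx = np.flatnonzero(eligible)
                if elig_idx.size == 0:
                    break
                for _try in range(50):
                    cand = int(elig_idx[rng.integers(0, elig_idx.size)])
                    if not is_del:
                        pos = cand
                        break
                    if cand + length <= len(st.seq) and bool(
                        (((st.region[cand : cand + length] == 0) | (st.region[cand : cand + length] == 2))
                         & ~st.in_gene[cand : cand + length]).all()
                    ):
                        pos = cand
                        break
                if pos < 0:
                    continue
                if is_del:
                    sl = slice(pos, pos + length)
                    st.seq = np.delete(st.seq, sl)
                    st.region = np.delete(st.region, sl)
                    st.in_gene = np.delete(st.in_gene, sl)
                    st.mult = np.delete(st.mult, sl)
                    for f in st.features:
                        for e in f[3]:
                            e[0] -= min(length, max(0, e[0] - pos))
                            e[1] -= min(length, max(0, e[1] - pos))
                else:
                    ins = rng.integers(0, 4, length).astype(np.uint8)
                    st.seq = np.insert(st.seq, pos, ins)
                    st.region = np.insert(st.region, pos, np.full(length, st.region[pos]))
                    st.in_gene = np.insert(st.in_gene, pos, np.zeros(length, dtype=bool))
                    st.mult = np.insert(st.mult, pos, np.full(length, st.mult[pos]))
                    for f in st.features:
                        for e in f[3]:
                            if e[0] >= pos:
                                e[0] += length
                            if e[1] > pos:
                                e[1] += length
                eligible = ((st.region == 0) | (st.region == 2)) & ~st.in_gene
        # re-mirror IRa from IRb
        irb_idx = np.flatnonzero(st.region == 1)
        ira_idx = np.flatnonzero(st.region == 3)
        st.seq[ira_idx] = (3 - st.seq[irb_idx])[::-1]
    return st


def _state_to_plastome(state: _State, name: str) -> Plastome:
    n = len(state.seq)
    seq = _BASE[state.seq].tobytes().decode()
    feats = []
    for fname, kind, strand, exons in state.features:
        ivs = [make_interval(s, e, n) for s, e in exons]
        feats.append(GeneFeature(fname, kind, ivs, strand))
    bounds = {}
    for code, rname in enumerate(("LSC", "IRb", "SSC", "IRa")):
        idx = np.flatnonzero(state.region == code)
        bounds[rname] = (int(idx[0]), int(idx[-1]) + 1)
    part = QuadripartitePartition(
        lsc=make_interval(*bounds["LSC"], n),
        irb=make_interval(*bounds["IRb"], n),
        ssc=make_interval(*bounds["SSC"], n),
        ira=make_interval(bounds["IRa"][0], bounds["IRa"][1] % n, n),
        genome_length=n,
    )
    return Plastome(id=name, seq=seq, features=feats, partition=part)


def evolve_along_tree(
    ancestor: Plastome,
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> list[Plastome]:
    """Evolve the ancestor along ``config.tree``; returns leaf plastomes in
    newick leaf order.  Deterministic for a fixed (config, seed)."""
    if not config.tree:
        raise ConfigError("config.tree is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = parse_newick(config.tree)
    root_state = _state_from_plastome(ancestor, truth)
    leaves: list[Plastome] = []

    def rec(node: TreeNode, state: _State) -> None:
        for child in node.children:
            st = _apply_branch(state, child.length, config, rng)
            if child.is_leaf():
                leaves.append(_state_to_plastome(st, child.name))
            else:
                rec(child, st)

    rec(tree, root_state)
    return leaves


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def default_preset(**overrides) -> SimulationConfig:
    """Small quadripartite genome with every structural element planted."""
    genes = [
        GeneSpec("psbZ", "CDS", "LSC", 300),
        GeneSpec("rpoX", "CDS", "LSC", 600),
        GeneSpec("atpQ", "CDS", "LSC", 300, n_exons=2, intron_length=80),
        GeneSpec("trnQ-UUG", "tRNA", "LSC", 72),
        GeneSpec("ndhZ", "CDS", "SSC", 300, strand="-"),
        GeneSpec("rrn9", "rRNA", "IRb", 200),
        GeneSpec("trnX-ABC", "tRNA", "IRb", 74),
        GeneSpec("rps19", "CDS", "LSC", 279, junction_bp=120),
    ]
    cfg = SimulationConfig(
        genome_length=20000,
        ir_length=3000,
        ssc_length=2000,
        genes=genes,
        planted_ssrs=[("A", 12), ("AT", 6), ("AAG", 5), ("ACGT", 4)],
        planted_dispersed=[("forward", 35), ("palindromic", 40)],
        planted_tandems=[("ACGTACGTAT", 4)],
        tree="((L1:0.01,L2:0.01):0.005,(L3:0.008,L4:0.008):0.005);",
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def hotspot_preset(n_spacer_genes: int = 16, **overrides) -> SimulationConfig:
    """Genome whose LSC spacers carry graded substitution multipliers; three
    spacers are 10x hotspots."""
    genes = [GeneSpec(f"g{i:02d}", "CDS", "LSC", 150) for i in range(1, n_spacer_genes + 1)]
    genes.append(GeneSpec("ndhZ", "CDS", "SSC", 150))
    grades = [0.4, 0.7, 1.0, 1.3, 1.6, 2.0, 2.4, 2.8, 3.2, 3.6, 4.0, 4.5]
    mults: dict[str, float] = {}
    hot = {3, 8, 13}  # spacer indices planted at 10x
    gi = 0
    for i in range(1, n_spacer_genes):
        name = f"g{i:02d}-g{i + 1:02d}"
        if i in hot:
            mults[name] = 10.0
        else:
            mults[name] = grades[gi % len(grades)]
            gi += 1
    cfg = SimulationConfig(
        genome_length=12000,
        ir_length=1500,
        ssc_length=1200,
        genes=genes,
        spacer_multipliers=mults,
        indel_rate=2e-4,
        tree="((A:0.012,B:0.012):0.006,(C:0.01,D:0.01):0.006,E:0.016);",
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def barcode_preset(**overrides) -> SimulationConfig:
    """5 species / 13 individuals with species-monophyletic truth and three
    high-rate marker spacers."""
    genes = [GeneSpec(f"g{i:02d}", "CDS", "LSC", 150) for i in range(1, 9)]
    mults = {"g02-g03": 10.0, "g04-g05": 10.0, "g06-g07": 10.0}
    tip = ":0.001"
    sp = {
        "sp1": ["sp1a", "sp1b", "sp1c"],
        "sp2": ["sp2a", "sp2b", "sp2c"],
        "sp3": ["sp3a", "sp3b", "sp3c"],
        "sp4": ["sp4a", "sp4b"],
        "sp5": ["sp5a", "sp5b"],
    }
    clades = {
        name: "(" + ",".join(m + tip for m in members) + "):0.02"
        for name, members in sp.items()
    }
    tree = (
        f"(({clades['sp1']},{clades['sp2']}):0.01,"
        f"({clades['sp3']},({clades['sp4']},{clades['sp5']}):0.008):0.01);"
    )
    species_map = {m: s for s, members in sp.items() for m in members}
    cfg = SimulationConfig(
        genome_length=9000,
        ir_length=1500,
        ssc_length=1200,
        genes=genes,
        spacer_multipliers=mults,
        tree=tree,
        species_map=species_map,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
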