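"""Distance-based discrimination checks: p-distances with pairwise
deletion, neighbor-joining, Robinson-Foulds distance, and a species-cluster
exclusivity test for candidate barcode marker sets."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .hotspots import RegionAlignment


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: list[list[float]]

    def __post_init__(self) -> None:
        n = len(self.taxa)
        for i in range(n):
            if abs(self.d[i][i]) > 1e-12:
                raise ValueError("nonzero diagonal")
            for j in range(n):
                if abs(self.d[i][j] - self.d[j][i]) > 1e-9:
                    raise ValueError("asymmetric distance matrix")
                if self.d[i][j] < 0:
                    raise ValueError("negative distance")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c._newick_inner() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6g}"


def parse_newick(text: str) -> TreeNode:
    """Minimal newick parser (names, branch lengths, nesting)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                elif s[pos] == ")":
                    pos += 1
                    break
        # optional label, then optional :branch_length
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        if s[start:pos]:
            node.name = s[start:pos]
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            node.length = float(s[start:pos])
        return node

    return parse_node()


def p_distance_matrix(alignments: list[RegionAlignment]) -> DistanceMatrix:
    """Pairwise p-distances over regions concatenated by name order, with
    pairwise deletion of columns holding a gap or N in either row."""
    if not alignments:
        raise ValueError("no alignments given")
    taxa = alignments[0].taxa
    for a in alignments:
        if a.taxa != taxa:
            raise ValueError("alignments disagree on taxa")
    ordered = sorted(alignments, key=lambda a: a.name)
    concat = ["".join(a.rows[i] for a in ordered) for i in range(len(taxa))]
    n = len(taxa)
    d = [[0.0] * n for _ in range(n)]
    skip = set("-N")
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            mism = 0
            for a, b in zip(concat[i], concat[j]):
                if a in skip or b in skip:
                    continue
                comparable += 1
                if a != b:
                    mism += 1
            if comparable == 0:
                raise ValueError(f"no comparable sites for pair ({taxa[i]}, {taxa[j]})")
            d[i][j] = d[j][i] = mism / comparable
    return DistanceMatrix(list(taxa), d)


def jc_distance_matrix(alignments: list[RegionAlignment]) -> DistanceMatrix:
    """Jukes-Cantor transform of the p-distance matrix."""
    pm = p_distance_matrix(alignments)
    n = len(pm.taxa)
    d = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            p = pm.d[i][j]
            if p >= 0.75:
                raise ValueError("saturated p-distance, JC undefined")
            d[i][j] = -0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0
    return DistanceMatrix(pm.taxa, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking (by the
    sorted name pair) and negative branch lengths clamped to zero."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    names = list(dm.taxa)
    d = {
        (i, j): dm.d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j
    }
    active = list(range(n))
    next_id = n
    node_of = {i: nodes[i] for i in range(n)}

    def dist(a, b):
        return d[(a, b)] if a != b else 0.0

    while len(active) > 2:
        r = len(active)
        row_sum = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * dist(a, b) - row_sum[a] - row_sum[b]
                key = (q, tuple(sorted((names[a], names[b]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (row_sum[a] - row_sum[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = TreeNode()
        ca, cb = node_of[a], node_of[b]
        ca.length, cb.length = la, lb
        parent.children = [ca, cb]
        u = next_id
        next_id += 1
        node_of[u] = parent
        names.append(f"__internal{u}")
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [u]
    a, b = active
    root = TreeNode()
    ca, cb = node_of[a], node_of[b]
    half = dist(a, b) / 2.0
    ca.length = cb.length = max(half, 0.0)
    root.children = [ca, cb]
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the side not containing the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaves())
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode):
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset()
        for c in node.children:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            out.add(side)
        return below

    walk(tree)
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Count of bipartitions present in exactly one of the two trees."""
    if set(t1.leaves()) != set(t2.leaves()):
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def marker_discrimination(
    tree: TreeNode, species_map: dict[str, str]
) -> tuple[bool, list[dict]]:
    """True iff every species with >= 2 individuals forms an exclusive
    cluster (its individuals appear as a bipartition side of the tree)."""
    leaves = set(tree.leaves())
    missing = set(species_map) - leaves
    if missing:
        raise ValueError(f"species map names absent from tree: {sorted(missing)}")
    bips = bipartitions(tree)
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    by_species: dict[str, set[str]] = {}
    for indiv, sp in species_map.items():
        by_species.setdefault(sp, set()).add(indiv)
    report = []
    ok = True
    for sp, members in sorted(by_species.items()):
        if len(members) < 2:
            report.append({"species": sp, "n": len(members), "status": "untestable"})
            continue
        side = frozenset(members)
        if len(side) >= len(all_leaves) - 1:
            exclusive = len(side) == len(all_leaves) - 1 or side == all_leaves
        else:
            canon = side if ref not in side else all_leaves - side
            exclusive = canon in bips
        report.append(
            {
                "species": sp,
                "n": len(members),
                "status": "exclusive" if exclusive else "not_exclusive",
            }
        )
        if not exclusive:
            ok = False
    return ok, report
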