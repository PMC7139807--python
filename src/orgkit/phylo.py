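"""Duplicate-copy phylogenetics for organelle-to-nucleus gene transfers.

A functional transfer leaves two copies of a gene in the cell: the
original organelle copy and a faster-evolving nuclear copy. Given an
alignment of such copies labelled by taxon and compartment, this module
builds a distance tree (JC69 or K2P, neighbor-joining), roots it with
outgroups, and asks the question the copy phylogeny exists to answer: how
many independent transfer events explain the placement of the nuclear
copies, and how much faster do they evolve?

Labels follow the "taxon|compartment" or "taxon|compartment|chromosome"
convention, compartment in {mt, nuc}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MITOCHONDRIAL = "mt"
NUCLEAR = "nuc"
_GAPS = {"-", "N", "?"}


def compartment_of(label: str) -> str:
    parts = label.split("|")
    if len(parts) < 2 or parts[1] not in (MITOCHONDRIAL, NUCLEAR):
        raise ValueError(
            f"label {label!r} must be 'taxon|mt' or 'taxon|nuc[|chromosome]'"
        )
    return parts[1]


@dataclass
class CopyAlignment:
    """Equal-length aligned gene copies with compartment-bearing labels."""

    labels: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.seqs):
            raise ValueError("labels and sequences differ in number")
        lens = {len(s) for s in self.seqs}
        if len(lens) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lens)}")
        for lab in self.labels:
            compartment_of(lab)

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def drop_gappy_columns(self, max_gap_frac: float = 0.5) -> "CopyAlignment":
        cols = []
        for j in range(self.n_sites):
            gaps = sum(1 for s in self.seqs if s[j] in _GAPS)
            if gaps / len(self.seqs) <= max_gap_frac:
                cols.append(j)
        return CopyAlignment(
            labels=list(self.labels),
            seqs=["".join(s[j] for j in cols) for s in self.seqs],
        )

    def resample_columns(self, rng: np.random.Generator) -> "CopyAlignment":
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        M = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            len(self.seqs), self.n_sites
        )[:, idx]
        return CopyAlignment(
            labels=list(self.labels),
            seqs=[row.tobytes().decode() for row in M],
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for lab, s in zip(self.labels, self.seqs):
                fh.write(f">{lab}\n{s}\n")

    @classmethod
    def from_fasta(cls, path) -> "CopyAlignment":
        labels, seqs = [], []
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        labels.append(name)
                        seqs.append("".join(chunks).upper())
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
        if name is not None:
            labels.append(name)
            seqs.append("".join(chunks).upper())
        return cls(labels=labels, seqs=seqs)


# ---------------------------------------------------------------------------
# distances

_PURINES = {"A", "G"}


def pairwise_distance(seq_a: str, seq_b: str, model: str = "jc") -> float:
    """Substitutions/site between two aligned sequences (gaps pair-deleted).

    JC69: d = -(3/4) ln(1 - 4p/3). K2P separates transitions (P) and
    transversions (Q): d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)).
    Saturated comparisons (non-positive log argument) return inf.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences are not aligned (unequal lengths)")
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a in _GAPS or b in _GAPS:
            continue
        n += 1
        if a != b:
            if (a in _PURINES) == (b in _PURINES):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable (non-gap) sites")
    if model == "jc":
        p = (ts + tv) / n
        arg = 1.0 - 4.0 * p / 3.0
        return math.inf if arg <= 0 else -0.75 * math.log(arg)
    if model == "k2p":
        P, Q = ts / n, tv / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return math.inf
        return -0.5 * math.log(a1 * math.sqrt(a2))
    raise ValueError(f"unknown model {model!r} (expected 'jc' or 'k2p')")


def distance_matrix(aln: CopyAlignment, model: str = "jc") -> np.ndarray:
    """All pairwise distances, vectorized (same formulas as pairwise_distance)."""
    k = len(aln.labels)
    M = np.frombuffer("".join(aln.seqs).encode(), dtype=np.uint8).reshape(
        k, aln.n_sites
    )
    gap = np.isin(M, np.frombuffer(b"-N?", dtype=np.uint8))
    purine = np.isin(M, np.frombuffer(b"AG", dtype=np.uint8))
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            keep = ~gap[i] & ~gap[j]
            n = int(keep.sum())
            if n == 0:
                raise ValueError(
                    f"no comparable sites between {aln.labels[i]} and {aln.labels[j]}"
                )
            diff = (M[i] != M[j]) & keep
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            if model == "jc":
                arg = 1.0 - 4.0 * (ts + tv) / (3.0 * n)
                d = math.inf if arg <= 0 else -0.75 * math.log(arg)
            elif model == "k2p":
                a1 = 1.0 - 2.0 * ts / n - tv / n
                a2 = 1.0 - 2.0 * tv / n
                d = (math.inf if a1 <= 0 or a2 <= 0
                     else -0.5 * math.log(a1 * math.sqrt(a2)))
            else:
                raise ValueError(f"unknown model {model!r} (expected 'jc' or 'k2p')")
            D[i, j] = D[j, i] = d
    return D


# ---------------------------------------------------------------------------
# trees

@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                sup = ""
                if with_support and node.support is not None and not top:
                    sup = f"{node.support:g}"
                body = f"({inner}){sup}"
            if top:
                return body
            return f"{body}:{node.length:.6f}"

        return fmt(self, True) + ";"


def from_newick(text: str) -> Node:
    """Parse a newick string (names, branch lengths, internal labels)."""
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # name / internal label
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        label = text[start:pos].strip()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    tree = parse_node()
    return tree


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> Node:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Labels are sorted first so the agglomeration order (and thus the
    resolution of exact ties in the Q criterion) is independent of input
    order. Negative branch-length estimates are clamped to zero with the
    deficit moved to the sister edge. Returns an unrooted tree as a
    trifurcating root node.
    """
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 taxa")
    if D.shape != (k, k):
        raise ValueError("distance matrix does not match label count")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances (saturated pairs?); cannot build tree")
    if not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    order = sorted(range(k), key=lambda i: labels[i])
    D = D[np.ix_(order, order)].astype(float)
    nodes: list[Node] = [Node(name=labels[i]) for i in order]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]

    root = Node(children=list(nodes))
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        nodes[0].length = max(0.0, 0.5 * (d01 + d02 - d12))
        nodes[1].length = max(0.0, 0.5 * (d01 + d12 - d02))
        nodes[2].length = max(0.0, 0.5 * (d02 + d12 - d01))
    elif len(nodes) == 2:
        nodes[0].length = D[0, 1] / 2
        nodes[1].length = D[0, 1] / 2
    return root


def build_tree(aln: CopyAlignment, model: str = "jc") -> Node:
    tree = neighbor_joining(distance_matrix(aln, model), aln.labels)
    lengths = [n.length for n in tree.walk() if n is not tree and n.length > 0]
    if lengths:
        med = float(np.median(lengths))
        long = [n for n in tree.walk() if n is not tree and n.length > 3 * med]
        if long:
            warnings.warn(
                f"{len(long)} branch(es) exceed 3x the median length; "
                "placements may be affected by long-branch attraction",
                stacklevel=2,
            )
    return tree


# ---------------------------------------------------------------------------
# rooting

def _edges(tree: Node) -> list[tuple[Node, Node]]:
    out = []
    for node in tree.walk():
        for c in node.children:
            out.append((node, c))
    return out


def root_with_outgroup(tree: Node, outgroup: Sequence[str]) -> Node:
    """Root an unrooted NJ tree on the edge separating the outgroup.

    The outgroup must be present; if it is monophyletic in the unrooted
    sense the root goes at the midpoint of the separating edge, otherwise
    the pendant edge of the first outgroup leaf is used.
    """
    og = set(outgroup)
    all_leaves = set(tree.leaf_names())
    missing = og - all_leaves
    if missing:
        raise ValueError(f"outgroup taxa absent from tree: {sorted(missing)}")
    target = None
    for parent, child in _edges(tree):
        below = set(child.leaf_names())
        if below == og or below == all_leaves - og:
            target = (parent, child)
            break
    if target is None:
        for parent, child in _edges(tree):
            if child.is_leaf and child.name == sorted(og)[0]:
                target = (parent, child)
                break
    parent, child = target
    return _reroot_on_edge(tree, child)


def _reroot_on_edge(tree: Node, child: Node) -> Node:
    """Return a new rooted tree with the root at the midpoint of the edge
    above `child`."""
    parents: dict[int, Node | None] = {id(tree): None}
    for node in tree.walk():
        for c in node.children:
            parents[id(c)] = node

    def flipped(node: Node, skip: Node | None) -> Node:
        """Copy of the tree as seen from `node`, walking away from skip."""
        new = Node(name=node.name, support=node.support)
        for c in node.children:
            if c is skip:
                continue
            cc = flipped(c, node)
            cc.length = c.length
            new.children.append(cc)
        par = parents[id(node)]
        if par is not None and par is not skip:
            pp = flipped(par, node)
            pp.length = node.length
            pp.support = node.support
            new.children.append(pp)
        return new

    half = child.length / 2.0
    top = Node()
    left = flipped(child, parents[id(child)])
    left.length = half
    right = flipped(parents[id(child)], child)
    right.length = half
    top.children = [left, right]
    # collapse pass-through nodes created at the old trifurcating root
    def collapse(n: Node) -> None:
        new_children = []
        for c in n.children:
            collapse(c)
            if not c.is_leaf and len(c.children) == 1:
                only = c.children[0]
                only.length += c.length
                new_children.append(only)
            else:
                new_children.append(c)
        n.children = new_children

    collapse(top)
    return top


# ---------------------------------------------------------------------------
# transfer counting and rate contrast

def count_transfer_events(
    rooted: Node, compartments: dict[str, str] | None = None
) -> tuple[int, list[list[str]]]:
    """Minimum number of organelle-to-nucleus transfer events on the tree.

    Equal to the number of maximal nuclear-only clades: each such clade is
    most parsimoniously explained by one mitochondrion-to-nucleus state
    change on its stem (reversals are not biologically available, so this
    is the Fitch minimum for an irreversible character). Returns the count
    and the taxa of each clade.
    """
    if compartments is None:
        compartments = {l: compartment_of(l) for l in rooted.leaf_names()}

    clades: list[list[str]] = []

    def visit(node: Node) -> bool:
        """True if every leaf below is nuclear (and none reported yet)."""
        if node.is_leaf:
            return compartments[node.name] == NUCLEAR
        flags = [visit(c) for c in node.children]
        if all(flags):
            return True
        for c, f in zip(node.children, flags):
            if f:
                clades.append(c.leaf_names())
        return False

    if visit(rooted):
        clades.append(rooted.leaf_names())
    return len(clades), clades


@dataclass
class RateContrast:
    ratio: float
    nuclear_mean_depth: float
    mito_mean_depth: float
    ci_low: float | None = None
    ci_high: float | None = None
    flagged: str | None = None


def _mean_depths(rooted: Node, compartments: dict[str, str]) -> tuple[float, float]:
    depths: dict[str, float] = {}

    def walk(node: Node, acc: float) -> None:
        acc += node.length
        if node.is_leaf:
            depths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(rooted, -rooted.length)
    nuc = [d for l, d in depths.items() if compartments[l] == NUCLEAR]
    mito = [d for l, d in depths.items() if compartments[l] == MITOCHONDRIAL]
    if not nuc or not mito:
        raise ValueError("need at least one leaf in each compartment class")
    return float(np.mean(nuc)), float(np.mean(mito))


def rate_acceleration(
    aln: CopyAlignment,
    outgroup: Sequence[str],
    model: str = "jc",
    n_boot: int = 1000,
    seed: int = 0,
) -> RateContrast:
    """Nuclear / mitochondrial mean root-to-tip rate ratio with bootstrap CI.

    The point estimate comes from the NJ tree of the full alignment; the
    interval from `n_boot` column-resampled replicates (percentile 2.5 and
    97.5). A single-leaf class is estimated but flagged.
    """
    compartments = {l: compartment_of(l) for l in aln.labels}
    tree = root_with_outgroup(build_tree(aln, model), outgroup)
    nuc, mito = _mean_depths(tree, compartments)
    ratio = nuc / mito if mito > 0 else math.inf
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        rep = aln.resample_columns(rng)
        try:
            t = root_with_outgroup(build_tree(rep, model), outgroup)
            n_, m_ = _mean_depths(t, compartments)
            if m_ > 0:
                reps.append(n_ / m_)
        except ValueError:
            continue
    flagged = None
    n_nuc = sum(1 for v in compartments.values() if v == NUCLEAR)
    n_mito = sum(1 for v in compartments.values() if v == MITOCHONDRIAL)
    if min(n_nuc, n_mito) == 1:
        flagged = "single-leaf compartment class: interval unreliable"
    lo = hi = None
    if reps:
        lo, hi = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return RateContrast(
        ratio=ratio, nuclear_mean_depth=nuc, mito_mean_depth=mito,
        ci_low=lo, ci_high=hi, flagged=flagged,
    )


def _bipartitions(tree: Node) -> set[frozenset[str]]:
    all_leaves = frozenset(tree.leaf_names())
    out = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        below = frozenset(node.leaf_names())
        side = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(frozenset(side))
    return out


def bootstrap_support(
    aln: CopyAlignment, model: str = "jc", n_boot: int = 100, seed: int = 0
) -> Node:
    """NJ tree with internal-edge bootstrap support percentages.

    Deterministic for a fixed seed: identical seeds give identical support
    values.
    """
    tree = build_tree(aln, model)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    done = 0
    for _ in range(n_boot):
        rep = aln.resample_columns(rng)
        try:
            bp = _bipartitions(build_tree(rep, model))
        except ValueError:
            continue
        done += 1
        for b in bp:
            counts[b] = counts.get(b, 0) + 1
    all_leaves = frozenset(tree.leaf_names())
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        below = frozenset(node.leaf_names())
        side = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
        if 1 < len(below) < len(all_leaves) - 1 and done:
            node.support = round(100.0 * counts.get(frozenset(side), 0) / done, 1)
    return tree
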