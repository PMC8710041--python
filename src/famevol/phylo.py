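"""Protein-guided codon alignment, neighbor-joining trees with bootstrap,
clade partitioning, and clade-based homolog calling.

The tree workflow follows the classic gene-family recipe: align proteins,
back-translate to codons, compute p-distances with pairwise deletion of
gapped/ambiguous sites, build a Saitou–Nei neighbor-joining tree, attach
bootstrap supports from site resampling, root on the outgroup (or at the
midpoint when the outgroup genes are scattered across clades, as they are
in a gene-family tree), and partition the tree into clades that (i) contain
at least one outgroup gene and (ii) contain genes from at least
``min_ingroup_species`` ingroup species.  Each accepted clade is read as
one ancestral gene copy.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .identify import translate_cds

__all__ = [
    "Node",
    "SupportTree",
    "CodonAlignment",
    "CladePartition",
    "codon_align",
    "pdistance_matrix",
    "neighbor_joining",
    "nj_tree",
    "partition_clades",
    "call_homologs",
]

_NEG = -1e30


# ---------------------------------------------------------------------------
# tree structure


class Node:
    """Tree node; ``support`` (0–100) belongs to the edge above the node."""

    __slots__ = ("name", "length", "children", "support")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def newick(self, with_support: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.6f}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if with_support and n.support is not None:
                label = f"{n.support:g}"
            return f"({inner}){label}:{n.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


@dataclass
class SupportTree:
    """A (possibly unrooted) gene tree with bootstrap supports on edges."""

    root: Node
    gene_ids: list[str]

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def newick(self, with_support: bool = True) -> str:
        return self.root.newick(with_support)

    @classmethod
    def from_newick(cls, newick: str) -> "SupportTree":
        import dendropy

        t = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dn) -> Node:
            n = Node()
            if dn.taxon is not None:
                n.name = dn.taxon.label.replace(" ", "_")
            elif dn.label is not None:
                try:
                    n.support = float(dn.label)
                except ValueError:
                    n.name = dn.label
            n.length = float(dn.edge.length) if dn.edge.length is not None else 0.0
            n.children = [convert(c) for c in dn.child_nodes()]
            return n

        root = convert(t.seed_node)
        return cls(root, sorted(root.leaf_names()))

    def rooted(
        self,
        outgroup_leaves: Iterable[str] | None = None,
    ) -> "SupportTree":
        """Return a rooted copy.

        If the outgroup leaves form one side of an edge the root is placed
        at that edge's midpoint; otherwise the tree is midpoint-rooted on
        its longest leaf-to-leaf path.
        """
        if self.is_rooted:
            return self
        root = _copy_tree(self.root)
        og = frozenset(outgroup_leaves or ())
        all_leaves = root.leaf_names()
        edge = None
        if og and og < all_leaves:
            for node in root.walk():
                if node is root:
                    continue
                side = node.leaf_names()
                if side == og or side == all_leaves - og:
                    edge = node
                    break
        if edge is not None:
            new_root = _reroot_on_edge(root, edge, edge.length / 2.0)
        else:
            new_root = _midpoint_root(root)
        return SupportTree(new_root, list(self.gene_ids))


def _copy_tree(node: Node) -> Node:
    n = Node(node.name, node.length)
    n.support = node.support
    n.children = [_copy_tree(c) for c in node.children]
    return n


def _parent_map(root: Node) -> dict[int, Node]:
    pm: dict[int, Node] = {}
    for n in root.walk():
        for c in n.children:
            pm[id(c)] = n
    return pm


def _reroot_on_edge(root: Node, child: Node, dist_from_child: float) -> Node:
    """Place a new root on the edge above `child`, `dist_from_child` away
    from it; flips the parent chain and suppresses the old root if it is
    left with a single child."""
    pm = _parent_map(root)
    path = [child]
    n = child
    while id(n) in pm:
        n = pm[id(n)]
        path.append(n)
    parent = path[1]
    parent.children.remove(child)
    new_root = Node()
    carry_len = child.length - dist_from_child
    carry_support = child.support
    child.length = dist_from_child
    new_root.children = [child, parent]
    cur = parent
    for nxt in path[2:]:
        nxt.children.remove(cur)
        cur.children.append(nxt)
        cur.length, carry_len = carry_len, cur.length
        cur.support, carry_support = carry_support, cur.support
        cur = nxt
    cur.length = carry_len
    cur.support = carry_support
    # the old root may now be a unifurcation (if the tree was already rooted)
    for n in new_root.walk():
        for i, c in enumerate(list(n.children)):
            if len(c.children) == 1:
                only = c.children[0]
                only.length += c.length
                if only.support is None:
                    only.support = c.support
                n.children[i] = only
    return new_root


def _midpoint_root(root: Node) -> Node:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    pm = _parent_map(root)

    def neighbors(n: Node) -> list[tuple[Node, float]]:
        out = [(c, c.length) for c in n.children]
        if id(n) in pm:
            p = pm[id(n)]
            out.append((p, n.length))
        return out

    def farthest(start: Node) -> tuple[Node, float, dict[int, Node]]:
        dist = {id(start): 0.0}
        prev: dict[int, Node] = {}
        stack = [start]
        best, bestd = start, 0.0
        while stack:
            n = stack.pop()
            for nb, w in neighbors(n):
                if id(nb) in dist:
                    continue
                dist[id(nb)] = dist[id(n)] + w
                prev[id(nb)] = n
                stack.append(nb)
                if nb.is_leaf and dist[id(nb)] > bestd:
                    best, bestd = nb, dist[id(nb)]
        return best, bestd, prev

    leaves = root.leaves()
    u, _, _ = farthest(leaves[0])
    v, diameter, prev = farthest(u)
    # walk back from v towards u until the midpoint
    path = [v]
    while id(path[-1]) in prev:
        path.append(prev[id(path[-1])])
    target = diameter / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        # undirected edge (a, b); length is that of whichever is the child
        child = a if pm.get(id(a)) is b else b
        w = child.length
        if acc + w >= target or (a, b) == (path[-2], path[-1]):
            offset = target - acc
            dist_from_child = offset if child is a else w - offset
            dist_from_child = min(max(dist_from_child, 0.0), w)
            return _reroot_on_edge(root, child, dist_from_child)
        acc += w
    raise RuntimeError("midpoint not found")  # pragma: no cover


# ---------------------------------------------------------------------------
# codon alignment

_PROT_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX-"
_PROT_INDEX = np.full(256, len(_PROT_ALPHABET) - 2, dtype=np.int64)  # default X
for _i, _c in enumerate(_PROT_ALPHABET):
    _PROT_INDEX[ord(_c)] = _i

_blosum = substitution_matrices.load("BLOSUM62")
_SUBMAT = np.zeros((len(_PROT_ALPHABET), len(_PROT_ALPHABET)))
for _i, _a in enumerate(_PROT_ALPHABET[:-1]):
    for _j, _b in enumerate(_PROT_ALPHABET[:-1]):
        _SUBMAT[_i, _j] = _blosum[_a, _b]
# gap columns score 0 against everything


@dataclass
class CodonAlignment:
    """Codon-aware nucleotide alignment (gaps in whole-codon triplets)."""

    gene_ids: list[str]
    rows: list[str]
    protein_rows: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    @classmethod
    def from_equal_length_cds(cls, records) -> "CodonAlignment":
        """Gap-free alignment from already-comparable equal-length CDS
        (e.g. simulator output, which contains no indels)."""
        ids = [r.gene_id for r in records]
        rows = [r.cds for r in records]
        if len({len(r) for r in rows}) > 1:
            raise ValueError("sequences differ in length; run codon_align")
        return cls(ids, rows)


def _profile_counts(rows: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(
        len(rows), -1
    )
    idx = _PROT_INDEX[arr]
    L = arr.shape[1]
    counts = np.zeros((L, len(_PROT_ALPHABET)))
    for k in range(len(_PROT_ALPHABET)):
        counts[:, k] = (idx == k).sum(axis=0)
    return counts


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Profile-profile global alignment (Gotoh affine gaps, average-of-pairs
    BLOSUM62 scoring).  Returns the two gap-extended row sets."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na, nb = len(rows_a), len(rows_b)
    S = (ca @ _SUBMAT @ cb.T) / (na * nb)
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in A (consume B)
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        ptrX[i, 0] = 1
    for j in range(1, lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        ptrY[0, j] = 2
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        # X can be filled vectorized (depends only on row i-1)
        fromM = Mi1 + gap_open
        fromX = Xi1 + gap_extend
        Xi[:] = np.maximum(fromM, fromX)
        ptrX[i] = np.where(fromX > fromM, 1, 0)
        Xi[0] = gap_open + (i - 1) * gap_extend
        ptrX[i, 0] = 1
        for j in range(1, lb + 1):
            best_prev = Mi1[j - 1]
            arg = 0
            if Xi1[j - 1] > best_prev:
                best_prev, arg = Xi1[j - 1], 1
            if Yi1[j - 1] > best_prev:
                best_prev, arg = Yi1[j - 1], 2
            Mi[j] = best_prev + Si[j - 1]
            ptrM[i, j] = arg
            ym = Mi[j - 1] + gap_open
            yy = Yi[j - 1] + gap_extend
            if yy > ym:
                Yi[j] = yy
                ptrY[i, j] = 2
            else:
                Yi[j] = ym
                ptrY[i, j] = 0
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ops: list[int] = []
    while i > 0 or j > 0:
        ops.append(state)
        if state == 0:
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            state = int(ptrX[i, j])
            i -= 1
        else:
            state = int(ptrY[i, j])
            j -= 1
    ops.reverse()
    out_a = []
    for row in rows_a:
        it = iter(row)
        out_a.append("".join(next(it) if op != 2 else "-" for op in ops))
    out_b = []
    for row in rows_b:
        it = iter(row)
        out_b.append("".join(next(it) if op != 1 else "-" for op in ops))
    return out_a, out_b


def _guide_distances(proteins: list[str]) -> np.ndarray:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _blosum
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    n = len(proteins)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(proteins[i], proteins[j])[0]
            ident = aln.counts().identities
            D[i, j] = D[j, i] = 1.0 - ident / max(aln.length, 1)
    return D


def codon_align(
    records, gap_open: float = -10.0, gap_extend: float = -0.5
) -> CodonAlignment:
    """Progressive protein alignment back-translated to codons.

    Records need ``gene_id`` and ``cds`` attributes.  Untranslatable records
    (internal stop codons, empty translation) are excluded with a warning.
    The guide tree is UPGMA over pairwise protein identity distances;
    profile merges use average-of-pairs BLOSUM62 scoring with affine gaps.
    Ungapping any output row recovers its input CDS exactly (trailing
    nucleotides beyond the translated region are re-appended, gap-padded to
    a codon boundary across rows).
    """
    kept = []
    for rec in records:
        protein, bad = translate_cds(rec.cds)
        if bad or not protein:
            warnings.warn(f"{rec.gene_id}: untranslatable CDS excluded from alignment")
            continue
        kept.append((rec.gene_id, rec.cds, protein))
    if len(kept) < 2:
        raise ValueError("need at least 2 translatable sequences")
    ids = [k[0] for k in kept]
    cdss = [k[1] for k in kept]
    prots = [k[2] for k in kept]

    if len(kept) == 2:
        a, b = _align_profiles([prots[0]], [prots[1]], gap_open, gap_extend)
        aligned = {0: a[0], 1: b[0]}
    else:
        D = _guide_distances(prots)
        condensed = D[np.triu_indices(len(prots), k=1)]
        Z = linkage(condensed, method="average")
        clusters: dict[int, tuple[list[int], list[str]]] = {
            i: ([i], [prots[i]]) for i in range(len(prots))
        }
        nxt = len(prots)
        for a_id, b_id, _, _ in Z:
            ia, pa = clusters.pop(int(a_id))
            ib, pb = clusters.pop(int(b_id))
            ra, rb = _align_profiles(pa, pb, gap_open, gap_extend)
            clusters[nxt] = (ia + ib, ra + rb)
            nxt += 1
        (indices, profile) = next(iter(clusters.values()))
        aligned = dict(zip(indices, profile))

    # back-translate each aligned protein row to codons
    codon_rows = []
    prot_rows = []
    for i in range(len(kept)):
        prow = aligned[i]
        prot_rows.append(prow)
        cds = cdss[i]
        ptr = 0
        parts = []
        for ch in prow:
            if ch == "-":
                parts.append("---")
            else:
                parts.append(cds[ptr : ptr + 3])
                ptr += 3
        parts.append(cds[ptr:])  # trailing stop codon / incomplete codon
        codon_rows.append("".join(parts))
    width = max(len(r) for r in codon_rows)
    width += (3 - width % 3) % 3
    codon_rows = [r + "-" * (width - len(r)) for r in codon_rows]
    return CodonAlignment(ids, codon_rows, prot_rows)


# ---------------------------------------------------------------------------
# distances and neighbor joining

_VALID_NT = np.zeros(256, dtype=bool)
for _c in b"ACGT":
    _VALID_NT[_c] = True


def _encode_rows(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer("".join(rows).upper().encode(), dtype=np.uint8).reshape(
        len(rows), -1
    )
    return arr, _VALID_NT[arr]


def _pdist_from_encoded(
    M: np.ndarray, V: np.ndarray, labels: Sequence[str], correction: str | None
) -> np.ndarray:
    shared = (V[:, None, :] & V[None, :, :]).sum(axis=-1)
    bad = np.argwhere(shared == 0)
    for i, j in bad:
        if i < j:
            raise ValueError(
                f"no shared ungapped sites between {labels[i]} and {labels[j]}"
            )
    diffs = ((M[:, None, :] != M[None, :, :]) & V[:, None, :] & V[None, :, :]).sum(
        axis=-1
    )
    P = diffs / np.maximum(shared, 1)
    np.fill_diagonal(P, 0.0)
    if correction == "jc":
        if (P >= 0.75).any():
            i, j = map(int, np.argwhere(P >= 0.75)[0])
            raise ValueError(
                f"Jukes-Cantor distance undefined (p >= 3/4) for "
                f"{labels[i]} vs {labels[j]}"
            )
        P = -0.75 * np.log1p(-4.0 * P / 3.0)
    return P


def pdistance_matrix(
    rows: list[str], labels: Sequence[str], correction: str | None = None
) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of non-ACGT sites.

    ``correction="jc"`` applies the Jukes–Cantor transform.
    """
    M, V = _encode_rows(rows)
    return _pdist_from_encoded(M, V, labels, correction)


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> Node:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    Equal Q values are resolved toward the lexicographically smallest pair
    of cluster labels (a cluster is labelled by its smallest leaf name), so
    the result is deterministic.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [Node(name=l) for l in labels]
    labs = list(labels)
    D = np.asarray(D, dtype=float).copy()
    while n > 3:
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(Q <= qmin + 1e-10)
        i, j = min(
            ((int(a), int(b)) for a, b in cands if a < b),
            key=lambda ij: tuple(sorted((labs[ij[0]], labs[ij[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        parent = Node()
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent.children = [nodes[i], nodes[j]]
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack(
            [
                np.hstack([D[np.ix_(keep, keep)], dnew[keep, None]]),
                np.hstack([dnew[keep], [0.0]]),
            ]
        )
        nodes = [nodes[k] for k in keep] + [parent]
        labs = [labs[k] for k in keep] + [min(labs[i], labs[j])]
        n -= 1
    root = Node()
    if n == 2:
        nodes[0].length = nodes[1].length = D[0, 1] / 2.0
        root.children = nodes
    else:
        la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
        lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
        lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
        for node, ln in zip(nodes, (la, lb, lc)):
            node.length = max(0.0, ln)
        root.children = nodes
    return root


def _bipartitions(root: Node) -> set[frozenset]:
    """Canonical nontrivial bipartitions (smaller side, ties by sorted
    tuple) of an unrooted tree."""
    all_leaves = root.leaf_names()
    out = set()
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        side = node.leaf_names()
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def nj_tree(
    alignment: CodonAlignment,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    correction: str | None = None,
) -> SupportTree:
    """Neighbor-joining tree with bootstrap supports.

    Distances are p-distances with pairwise deletion (Jukes–Cantor behind
    ``correction="jc"``).  Bootstrap replicates resample alignment columns
    with replacement; supports are the percentage of replicate trees
    containing each internal bipartition.  With ``n_bootstrap=0`` the tree
    is returned without supports.
    """
    if len(alignment.gene_ids) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    ids = alignment.gene_ids
    M, V = _encode_rows(alignment.rows)
    D = _pdist_from_encoded(M, V, ids, correction)
    tree = neighbor_joining(D, ids)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        L = M.shape[1]
        counts: Counter = Counter()
        for _ in range(n_bootstrap):
            idx = rng.integers(0, L, size=L)
            Db = _pdist_from_encoded(M[:, idx], V[:, idx], ids, correction)
            counts.update(_bipartitions(neighbor_joining(Db, ids)))
        all_leaves = frozenset(ids)
        for node in tree.walk():
            if node is tree or node.is_leaf:
                continue
            side = node.leaf_names()
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
            node.support = 100.0 * counts[canon] / n_bootstrap
    return SupportTree(tree, list(ids))


# ---------------------------------------------------------------------------
# clade partitioning and homolog calling


@dataclass
class CladePartition:
    """Tree leaves grouped into accepted clades; the rest are unassigned."""

    clades: dict[str, frozenset]
    flags: dict[str, dict]
    unassigned: frozenset

    def clade_of(self) -> dict[str, str]:
        out = {}
        for cid, genes in self.clades.items():
            for g in genes:
                out[g] = cid
        return out


def partition_clades(
    tree: SupportTree,
    species_of: Mapping[str, str],
    outgroup: str,
    min_ingroup_species: int = 5,
) -> CladePartition:
    """Partition a gene tree into clades under the two family criteria.

    A subtree qualifies iff it contains (i) at least one outgroup-species
    gene and (ii) genes from at least ``min_ingroup_species`` distinct
    ingroup species.  The search is deepest-first: a qualifying subtree is
    accepted only when no split below it yields two or more disjoint
    qualifying subtrees, so the finest partition consistent with the
    criteria is returned.  Leaves outside every accepted clade are reported
    unassigned.
    """
    og_leaves = [g for g in tree.gene_ids if species_of[g] == outgroup]
    if not og_leaves:
        raise ValueError("tree contains no outgroup genes")
    rooted = tree.rooted(og_leaves) if not tree.is_rooted else tree
    root = rooted.root

    def qualifies(leafset: frozenset) -> tuple[bool, bool, int]:
        species = {species_of[g] for g in leafset}
        has_og = outgroup in species
        n_in = len(species - {outgroup})
        return (has_og and n_in >= min_ingroup_species, has_og, n_in)

    accepted: list[frozenset] = []

    def collect(node: Node) -> list[frozenset]:
        if node.is_leaf:
            return []
        subs: list[frozenset] = []
        for c in node.children:
            subs.extend(collect(c))
        if len(subs) >= 2:
            return subs
        leafset = node.leaf_names()
        ok, _, _ = qualifies(leafset)
        if ok:
            return [leafset]
        return subs

    accepted = collect(root)
    clades: dict[str, frozenset] = {}
    flags: dict[str, dict] = {}
    assigned: set = set()
    for k, leafset in enumerate(accepted, start=1):
        cid = f"C{k}"
        _, has_og, n_in = qualifies(leafset)
        clades[cid] = leafset
        flags[cid] = {"has_outgroup_gene": has_og, "n_ingroup_species_present": n_in}
        assigned |= leafset
    unassigned = frozenset(set(tree.gene_ids) - assigned)
    return CladePartition(clades, flags, unassigned)


def call_homologs(
    tree: SupportTree,
    species_of: Mapping[str, str],
    reference_species: str,
    support_threshold: float = 50.0,
) -> dict[str, set]:
    """Clade-based homolog calling against a reference species.

    For each non-reference (query) gene, returns the reference genes in its
    smallest enclosing clade whose subtending node has bootstrap support at
    or above the threshold and which contains at least one reference gene.
    Nodes without a support value (including the root) never qualify; the
    set is empty when no such clade exists.
    """
    root = tree.root
    pm = _parent_map(root)
    ref_below: dict[int, set] = {}

    def fill(node: Node) -> set:
        if node.is_leaf:
            s = {node.name} if species_of[node.name] == reference_species else set()
        else:
            s = set()
            for c in node.children:
                s |= fill(c)
        ref_below[id(node)] = s
        return s

    fill(root)
    out: dict[str, set] = {}
    for leaf in root.leaves():
        if species_of[leaf.name] == reference_species:
            continue
        node = pm.get(id(leaf))
        homologs: set = set()
        while node is not None:
            if (
                node.support is not None
                and node.support >= support_threshold
                and ref_below[id(node)]
            ):
                homologs = set(ref_below[id(node)])
                break
            node = pm.get(id(node))
        out[leaf.name] = homologs
    return out
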