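"""Independent brute-force oracles used to validate the implementations.

Each oracle is deliberately naive (exhaustive enumeration, double loops,
closed forms) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

_NT = set("ACGT")

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def ng_pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    over minimal pathways, skipping stop-traversing paths when possible."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in itertools.permutations(diff):
        cur = ca
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _CODE[nxt] == "*":
                through_stop = True
                nd += 1
            elif _CODE[cur] == "*":
                nd += 1
            elif _CODE[cur] == _CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, t in results if not t]
    if not clean:
        clean = [(s, n) for s, n, _ in results]
    return (
        sum(s for s, _ in clean) / len(clean),
        sum(n for _, n in clean) / len(clean),
    )


def ng_syn_sites(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        hits = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _CODE[alt] != "*" and _CODE[alt] == _CODE[codon]:
                hits += 1
        s += hits / 3.0
    return s


def naive_pi(rows: list[str]) -> float:
    """Nucleotide diversity by explicit double loop."""
    n = len(rows)
    acc = 0.0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs = sites = 0
            for a, b in zip(rows[i].upper(), rows[j].upper()):
                if a in _NT and b in _NT:
                    sites += 1
                    if a != b:
                        diffs += 1
            acc += diffs / sites
            pairs += 1
    return acc / pairs


# --- exhaustive least-squares tree search ----------------------------------


def _unrooted_topologies(taxa: list[str]):
    """All unrooted binary topologies, as sets of nontrivial bipartitions.

    Built by stepwise insertion of each taxon on every edge; edges are
    represented as frozensets of leaf names on one side.
    """
    # a topology is a list of edges; each edge is a frozenset (one side)
    def splits(tree_edges, all_taxa):
        out = set()
        for e in tree_edges:
            other = frozenset(all_taxa) - e
            if len(e) >= 2 and len(other) >= 2:
                out.add(min(e, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return frozenset(out)

    # represent trees as adjacency over nodes to permit insertion
    class T:
        def __init__(self):
            self.adj: dict[int, set[int]] = {}
            self.leaf: dict[int, str] = {}
            self.n = 0

        def new_node(self, name=None):
            k = self.n
            self.n += 1
            self.adj[k] = set()
            if name:
                self.leaf[k] = name
            return k

        def connect(self, a, b):
            self.adj[a].add(b)
            self.adj[b].add(a)

        def copy(self):
            t = T()
            t.adj = {k: set(v) for k, v in self.adj.items()}
            t.leaf = dict(self.leaf)
            t.n = self.n
            return t

        def edges(self):
            seen = set()
            for a in self.adj:
                for b in self.adj[a]:
                    if (b, a) not in seen:
                        seen.add((a, b))
            return list(seen)

        def side(self, a, b):
            """Leaves on a's side of edge (a, b)."""
            stack, seen = [a], {a, b}
            out = set()
            while stack:
                x = stack.pop()
                if x in self.leaf:
                    out.add(self.leaf[x])
                for y in self.adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            return frozenset(out)

    base = T()
    center = base.new_node()
    for name in taxa[:3]:
        leaf = base.new_node(name)
        base.connect(center, leaf)
    trees = [base]
    for name in taxa[3:]:
        nxt = []
        for t in trees:
            for a, b in t.edges():
                t2 = t.copy()
                mid = t2.new_node()
                leaf = t2.new_node(name)
                t2.adj[a].discard(b)
                t2.adj[b].discard(a)
                t2.connect(a, mid)
                t2.connect(mid, b)
                t2.connect(mid, leaf)
                nxt.append(t2)
        trees = nxt
    out = []
    for t in trees:
        bps = set()
        for a, b in t.edges():
            s = t.side(a, b)
            o = frozenset(taxa) - s
            if len(s) >= 2 and len(o) >= 2:
                bps.add(min(s, o, key=lambda x: (len(x), tuple(sorted(x)))))
        out.append((t, frozenset(bps)))
    return out


def least_squares_topology(D: np.ndarray, taxa: list[str]) -> frozenset:
    """Bipartition set of the topology with the smallest least-squares fit
    of branch lengths to the distance matrix (exhaustive search)."""
    idx = {t: i for i, t in enumerate(taxa)}
    best_bps, best_rss = None, np.inf
    for t, bps in _unrooted_topologies(taxa):
        edges = t.edges()
        pairs = list(itertools.combinations(taxa, 2))
        A = np.zeros((len(pairs), len(edges)))
        d = np.zeros(len(pairs))
        for r, (u, v) in enumerate(pairs):
            d[r] = D[idx[u], idx[v]]
            for c, (a, b) in enumerate(edges):
                side = t.side(a, b)
                if (u in side) != (v in side):
                    A[r, c] = 1.0
        x, rss, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(((A @ x - d) ** 2).sum())
        if resid < best_rss - 1e-12:
            best_rss, best_bps = resid, bps
    return best_bps


def all_additive_trees(taxa: list[str], rng: np.random.Generator):
    """One random-length additive distance matrix for EVERY unrooted
    topology over the taxa; yields (D, bipartition set) pairs."""
    idx = {name: i for i, name in enumerate(taxa)}
    for t, bps in _unrooted_topologies(taxa):
        D = np.zeros((len(taxa), len(taxa)))
        lengths = {
            frozenset((a, b)): float(rng.uniform(0.5, 3.0)) for a, b in t.edges()
        }
        for u, v in itertools.combinations(taxa, 2):
            total = 0.0
            for a, b in t.edges():
                side = t.side(a, b)
                if (u in side) != (v in side):
                    total += lengths[frozenset((a, b))]
            D[idx[u], idx[v]] = D[idx[v], idx[u]] = total
        yield D, bps


def random_additive_tree(taxa: list[str], rng: np.random.Generator):
    """Random binary tree with positive branch lengths; returns its
    distance matrix and bipartition set."""
    tops = _unrooted_topologies(taxa)
    t, bps = tops[rng.integers(0, len(tops))]
    idx = {name: i for i, name in enumerate(taxa)}
    D = np.zeros((len(taxa), len(taxa)))
    lengths = {frozenset((a, b)): float(rng.uniform(0.5, 3.0)) for a, b in t.edges()}
    for u, v in itertools.combinations(taxa, 2):
        total = 0.0
        for a, b in t.edges():
            side = t.side(a, b)
            if (u in side) != (v in side):
                total += lengths[frozenset((a, b))]
        D[idx[u], idx[v]] = D[idx[v], idx[u]] = total
    return D, bps
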