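"""Synthetic multi-species gene families with known ground truth.

The generator mirrors the design of a comparative gene-family study in a
clade of closely related species plus one outgroup: a fixed number of
ancestral gene copies is present at the root of the species tree, each copy
evolves by lineage-specific birth (duplication) and death (loss) along the
species-tree branches, and surviving leaves become genes.  All branch
lengths are expressed in Ks units (expected synonymous substitutions per
synonymous site), so "recent duplication" means small Ks depth and the
simulated clock is directly comparable to Ks estimated from sequences.

Three layers of ground truth are recorded: the full event log, the mapping
of every surviving gene to its ancestral copy (clade), and the true pairwise
synonymous distance between genes.  Codon sequences are then evolved over
the recorded gene trees under a simplified Goldman–Yang-style model with a
single nonsynonymous/synonymous rate ratio omega, and expression matrices
with planted pairwise Pearson correlations are drawn from a Gaussian copula
over log-normal marginals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._codons import (
    AA_TO_CODON,
    CODON_TO_AA,
    SENSE_CODONS,
    single_nt_neighbors,
    translate_codon,
)

__all__ = [
    "SpeciesTree",
    "SimConfig",
    "SimEvent",
    "SimTruth",
    "GeneNode",
    "ExpressionSimSpec",
    "simulate_family",
    "evolve_codons",
    "simulate_dataset",
    "simulate_decoys",
    "simulate_expression",
    "default_species_tree",
    "DEFAULT_MOTIF",
]

#: amino-acid motif embedded (and held invariant) in every simulated protein,
#: matching the family signature the identification stage scans for
DEFAULT_MOTIF = "FVTKVQELTG"


class _SpNode:
    __slots__ = ("name", "length", "children", "is_leaf")

    def __init__(self, name: str, length: float, children: list["_SpNode"]):
        self.name = name
        self.length = length
        self.children = children
        self.is_leaf = not children


@dataclass
class SpeciesTree:
    """Rooted species tree with branch lengths in Ks units.

    Parameters
    ----------
    newick
        Rooted tree over species labels; branch lengths are expected
        synonymous substitutions per synonymous site.
    outgroup
        Label of the single outgroup species (must be a leaf).
    """

    newick: str
    outgroup: str

    def __post_init__(self) -> None:
        tree = dendropy.Tree.get(data=self.newick, schema="newick")
        counter = [0]

        def convert(node) -> _SpNode:
            children = [convert(c) for c in node.child_nodes()]
            if node.taxon is not None:
                name = node.taxon.label.replace(" ", "_")
            elif node.label:
                name = node.label
            else:
                counter[0] += 1
                name = f"anc{counter[0]}"
            length = node.edge.length if node.edge.length is not None else 0.0
            if length < 0:
                raise ValueError(f"negative branch length on {name}")
            return _SpNode(name, float(length), children)

        self._root = convert(tree.seed_node)
        leaves = self.species
        if self.outgroup not in leaves:
            raise ValueError(f"outgroup {self.outgroup!r} is not a leaf of the tree")
        if len(leaves) - 1 < 2:
            raise ValueError("need at least 2 ingroup species")

    @property
    def root(self) -> _SpNode:
        return self._root

    @property
    def species(self) -> list[str]:
        out: list[str] = []

        def walk(n: _SpNode) -> None:
            if n.is_leaf:
                out.append(n.name)
            for c in n.children:
                walk(c)

        walk(self._root)
        return out

    @property
    def ingroup(self) -> list[str]:
        return [s for s in self.species if s != self.outgroup]


def default_species_tree() -> SpeciesTree:
    """Six-ingroup-species tree plus outgroup, Ks-unit branch lengths.

    Depths mimic a genus of closely related stone-fruit species (crown
    divergence around Ks 0.12–0.14) with a strawberry-like outgroup at
    roughly twice that depth.
    """
    nwk = (
        "((((Pper:0.02,Pdul:0.02):0.02,(Pavi:0.03,Pdom:0.03):0.01):0.03,"
        "(Pyed:0.03,Pnud:0.03):0.04):0.19,Fves:0.26);"
    )
    return SpeciesTree(newick=nwk, outgroup="Fves")


@dataclass
class SimConfig:
    """Parameters of the family simulator.

    ``n_ancestral_copies`` is the number of gene copies present in the
    common ancestor (one per eventual clade).  Birth and death rates are
    per gene lineage per unit Ks.  ``recent_burst`` is an optional
    ``(ks_offset, extra_birth_rate)`` pair adding duplication rate within
    ``ks_offset`` of the present on terminal branches, concentrating
    duplications near the tips.
    """

    n_ancestral_copies: int = 13
    birth_rate: float = 0.0
    death_rate: float = 0.0
    omega: float = 0.2
    codon_length: int = 150
    recent_burst: tuple[float, float] | None = None
    motif: str = DEFAULT_MOTIF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestral_copies < 1:
            raise ValueError("n_ancestral_copies must be >= 1")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.codon_length < 30:
            raise ValueError("codon_length must be >= 30")
        if self.recent_burst is not None:
            off, extra = self.recent_burst
            if off < 0 or extra < 0:
                raise ValueError("recent_burst values must be >= 0")


@dataclass(frozen=True)
class SimEvent:
    kind: str  # "duplication" | "loss"
    species_branch: str
    clade_id: int
    ks_depth: float  # distance from the species-tree root


class GeneNode:
    """Node of a simulated gene lineage tree (branch lengths in Ks)."""

    __slots__ = ("length", "children", "gene_id", "species", "extinct")

    def __init__(self, length: float = 0.0):
        self.length = length
        self.children: list[GeneNode] = []
        self.gene_id: str | None = None
        self.species: str | None = None
        self.extinct = False

    def leaves(self) -> list["GeneNode"]:
        if not self.children:
            return [self]
        out: list[GeneNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated family."""

    event_log: list[SimEvent]
    gene_to_clade: dict[str, int]
    pairwise_ks_true: dict[frozenset, float]
    gene_trees: dict[int, GeneNode] = field(default_factory=dict)

    def events_per_species(self, kind: str = "duplication") -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.event_log:
            if ev.kind == kind:
                out[ev.species_branch] = out.get(ev.species_branch, 0) + 1
        return out


def _piecewise_segments(
    length: float, terminal: bool, cfg: SimConfig
) -> list[tuple[float, float]]:
    """(segment_length, birth_rate) pieces along one species-tree branch."""
    if terminal and cfg.recent_burst is not None:
        off, extra = cfg.recent_burst
        off = min(off, length)
        head = length - off
        segs = []
        if head > 0:
            segs.append((head, cfg.birth_rate))
        if off > 0:
            segs.append((off, cfg.birth_rate + extra))
        return segs or [(length, cfg.birth_rate)]
    return [(length, cfg.birth_rate)]


def _evolve_lineage_on_branch(
    tip: GeneNode,
    segments: list[tuple[float, float]],
    cfg: SimConfig,
    rng: np.random.Generator,
    events: list[SimEvent],
    branch_label: str,
    clade_id: int,
    depth0: float,
) -> list[GeneNode]:
    """Birth–death on one branch for one entering lineage.

    Returns the open tips surviving to the end of the branch; `tip` is
    mutated in place (its length grows, children are attached on birth).
    """
    total = sum(s for s, _ in segments)
    # stack entries: (node, time within branch at which its segment starts)
    stack = [(tip, 0.0)]
    survivors: list[GeneNode] = []
    while stack:
        node, t0 = stack.pop()
        t = t0
        alive = True
        while t < total:
            # locate current segment and its birth rate
            acc = 0.0
            lam = segments[-1][1]
            seg_end = total
            for seg_len, seg_rate in segments:
                if t < acc + seg_len:
                    lam = seg_rate
                    seg_end = acc + seg_len
                    break
                acc += seg_len
            rate = lam + cfg.death_rate
            if rate <= 0:
                t = seg_end
                continue
            wait = rng.exponential(1.0 / rate)
            if t + wait >= seg_end:
                t = seg_end
                continue
            t = t + wait
            if rng.random() < lam / rate:
                # duplication: close this branch, open two children
                node.length += t - t0
                events.append(
                    SimEvent("duplication", branch_label, clade_id, depth0 + t)
                )
                left, right = GeneNode(), GeneNode()
                node.children = [left, right]
                stack.append((right, t))
                stack.append((left, t))
                alive = False
                break
            # loss
            node.length += t - t0
            node.extinct = True
            events.append(SimEvent("loss", branch_label, clade_id, depth0 + t))
            alive = False
            break
        if alive:
            node.length += total - t0
            survivors.append(node)
    return survivors


def _prune_extinct(node: GeneNode) -> GeneNode | None:
    """Remove extinct subtrees and suppress unifurcations."""
    if not node.children:
        return None if node.extinct else node
    kept = []
    for c in node.children:
        p = _prune_extinct(c)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.length += node.length
        return child
    node.children = kept
    return node


def _leaf_depths(node: GeneNode, depth: float = 0.0) -> list[tuple[GeneNode, float]]:
    d = depth + node.length
    if not node.children:
        return [(node, d)]
    out: list[tuple[GeneNode, float]] = []
    for c in node.children:
        out.extend(_leaf_depths(c, d))
    return out


def _pairwise_path_lengths(root: GeneNode) -> dict[frozenset, float]:
    """Path length (summed Ks) between every leaf pair of one gene tree."""
    out: dict[frozenset, float] = {}

    def walk(node: GeneNode, depth: float) -> list[tuple[str, float]]:
        d = depth + node.length
        if not node.children:
            return [(node.gene_id, d)]
        groups = [walk(c, d) for c in node.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for ga, da in groups[i]:
                    for gb, db in groups[j]:
                        out[frozenset((ga, gb))] = (da - d) + (db - d)
        merged: list[tuple[str, float]] = []
        for g in groups:
            merged.extend(g)
        return merged

    walk(root, -root.length)  # cancel the root's own stem
    return out


def simulate_family(
    tree: SpeciesTree, cfg: SimConfig
) -> tuple[dict[str, list[str]], SimTruth]:
    """Simulate one gene family over a species tree.

    Each ancestral copy seeds an independent gene lineage at the root;
    birth–death events are drawn along every species-tree branch in Ks-time.
    Returns per-species gene-id lists and the full ground truth (event log,
    gene-to-clade map, true pairwise Ks, and the pruned per-clade gene
    trees used by :func:`evolve_codons`).

    An all-extinct clade simply contributes no genes; it is not an error.
    """
    rng = np.random.default_rng(cfg.seed)
    events: list[SimEvent] = []
    gene_to_clade: dict[str, int] = {}
    pairwise: dict[frozenset, float] = {}
    gene_trees: dict[int, GeneNode] = {}
    per_species: dict[str, list[str]] = {sp: [] for sp in tree.species}
    counters: dict[str, int] = {sp: 0 for sp in tree.species}

    for clade_id in range(1, cfg.n_ancestral_copies + 1):
        root = GeneNode(0.0)

        def descend(sp_node: _SpNode, tips: list[GeneNode], depth: float) -> None:
            if sp_node.is_leaf:
                for tip in tips:
                    counters[sp_node.name] += 1
                    tip.gene_id = f"{sp_node.name}_c{clade_id:02d}_g{counters[sp_node.name]}"
                    tip.species = sp_node.name
                return
            for child in sp_node.children:
                segs = _piecewise_segments(child.length, child.is_leaf, cfg)
                next_tips: list[GeneNode] = []
                for tip in tips:
                    branch_tip = GeneNode(0.0)
                    tip.children.append(branch_tip)
                    next_tips.extend(
                        _evolve_lineage_on_branch(
                            branch_tip, segs, cfg, rng, events,
                            child.name, clade_id, depth,
                        )
                    )
                descend(child, next_tips, depth + child.length)

        descend(tree.root, [root], 0.0)
        pruned = _prune_extinct(root)
        if pruned is None:
            continue
        gene_trees[clade_id] = pruned
        for leaf in pruned.leaves():
            gene_to_clade[leaf.gene_id] = clade_id
            per_species[leaf.species].append(leaf.gene_id)
        pairwise.update(_pairwise_path_lengths(pruned))

    truth = SimTruth(events, gene_to_clade, pairwise, gene_trees)
    return per_species, truth


# ---------------------------------------------------------------------------
# codon evolution

# per-codon substitution machinery: neighbor lists and total exit rates are
# precomputed lazily per omega
_evolver_cache: dict[float, tuple[dict, dict]] = {}


def _evolver_tables(omega: float) -> tuple[dict, dict]:
    if omega not in _evolver_cache:
        rates: dict[str, np.ndarray] = {}
        targets: dict[str, list[str]] = {}
        for codon in SENSE_CODONS:
            nb = single_nt_neighbors(codon)
            targets[codon] = [alt for alt, _, _ in nb]
            # rate 1/3 per synonymous alternative makes one unit of branch
            # length equal one expected synonymous substitution per
            # synonymous (Nei-Gojobori) site; nonsynonymous scaled by omega.
            # NG counts changes to stop codons as nonsynonymous sites but the
            # evolver never performs them, so the nonsynonymous rate is
            # inflated by the stop fraction to keep the realized flux per NG
            # nonsynonymous site equal to omega.
            n_nonsyn_all = sum(
                1
                for pos in range(3)
                for nt in "ACGT"
                if nt != codon[pos]
                and not (
                    (alt := codon[:pos] + nt + codon[pos + 1 :]) in CODON_TO_AA
                    and CODON_TO_AA[alt] == CODON_TO_AA[codon]
                )
            )
            n_nonsyn_sense = sum(1 for _, _, syn in nb if not syn)
            stop_factor = n_nonsyn_all / n_nonsyn_sense if n_nonsyn_sense else 1.0
            r = np.array(
                [
                    (1.0 / 3.0) if syn else (omega / 3.0) * stop_factor
                    for _, _, syn in nb
                ]
            )
            rates[codon] = r
        _evolver_cache[omega] = (targets, rates)
    return _evolver_cache[omega]


def _random_root_codons(
    codon_length: int, motif: str, rng: np.random.Generator
) -> tuple[list[str], frozenset]:
    motif_codons = [AA_TO_CODON[aa] for aa in motif]
    n_random = codon_length - 1 - len(motif_codons)
    if n_random < 0:
        raise ValueError("codon_length too short for the embedded motif")
    idx = rng.integers(0, len(SENSE_CODONS), size=n_random)
    codons = ["ATG"] + motif_codons + [SENSE_CODONS[i] for i in idx]
    frozen = frozenset(range(1 + len(motif_codons)))
    return codons, frozen


def _evolve_codon(
    codon: str, t: float, targets: dict, rates: dict, rng: np.random.Generator
) -> str:
    remaining = t
    while True:
        r = rates[codon]
        total = r.sum()
        wait = rng.exponential(1.0 / total)
        if wait >= remaining:
            return codon
        remaining -= wait
        k = rng.choice(len(r), p=r / total)
        codon = targets[codon][k]


def evolve_codons(
    gene_tree: GeneNode,
    cfg: SimConfig,
    seed: int | None = None,
    root_codons: Sequence[str] | None = None,
) -> dict[str, str]:
    """Evolve codon sequences down one gene lineage tree.

    The root sequence starts with ATG followed by the embedded family motif
    (those codons are held invariant so that every descendant still carries
    the signature); the remainder is uniform over sense codons.  Each codon
    evolves independently by a continuous-time process in which single-
    nucleotide changes occur at rate 1/3 per synonymous alternative and
    omega/3 per nonsynonymous alternative; changes to stop codons never
    occur.  One unit of branch length therefore corresponds to one expected
    synonymous substitution per synonymous site (Ks) and the expected
    Ka/Ks of the process is omega.

    Returns ``{gene_id: cds}`` for the tree's leaves.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    targets, rates = _evolver_tables(cfg.omega)
    if root_codons is None:
        codons, frozen = _random_root_codons(cfg.codon_length, cfg.motif, rng)
    else:
        codons = list(root_codons)
        frozen = frozenset(range(1 + len(cfg.motif)))
    out: dict[str, str] = {}

    def walk(node: GeneNode, seq: list[str]) -> None:
        if node.length > 0:
            seq = [
                c if i in frozen else _evolve_codon(c, node.length, targets, rates, rng)
                for i, c in enumerate(seq)
            ]
        if not node.children:
            out[node.gene_id or "root"] = "".join(seq)
            return
        for child in node.children:
            walk(child, seq)

    walk(gene_tree, codons)
    return out


@dataclass
class SimulatedGene:
    gene_id: str
    species: str
    clade_id: int
    cds: str

    @property
    def protein(self) -> str:
        return "".join(
            translate_codon(self.cds[i : i + 3]) for i in range(0, len(self.cds), 3)
        )


def simulate_dataset(
    tree: SpeciesTree, cfg: SimConfig
) -> tuple[list[SimulatedGene], SimTruth]:
    """Full family simulation: birth–death history plus codon sequences.

    Every clade's root sequence is drawn independently, so different clades
    are deeply separated (near-saturated divergence) while within-clade
    divergence follows the species tree and duplication history — the
    regime of a family descended from long-separated ancestral copies.
    """
    per_species, truth = simulate_family(tree, cfg)
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    genes: list[SimulatedGene] = []
    for clade_id, gtree in sorted(truth.gene_trees.items()):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        seqs = evolve_codons(gtree, cfg, seed=sub_seed)
        for leaf in gtree.leaves():
            genes.append(
                SimulatedGene(leaf.gene_id, leaf.species, clade_id, seqs[leaf.gene_id])
            )
    genes.sort(key=lambda g: g.gene_id)
    return genes, truth


def simulate_decoys(
    n: int,
    codon_length: int = 150,
    seed: int = 0,
    forbidden_motifs: Iterable[str] = (DEFAULT_MOTIF, "WRKYGQK", "WRKYGKK"),
) -> list[SimulatedGene]:
    """Random coding sequences guaranteed to lack the family motifs.

    Used as negative controls for the identification stage.
    """
    rng = np.random.default_rng(seed)
    forbidden = tuple(forbidden_motifs)
    decoys: list[SimulatedGene] = []
    while len(decoys) < n:
        idx = rng.integers(0, len(SENSE_CODONS), size=codon_length - 1)
        cds = "ATG" + "".join(SENSE_CODONS[i] for i in idx)
        gene = SimulatedGene(f"decoy_g{len(decoys) + 1}", "decoy", 0, cds)
        if any(m in gene.protein for m in forbidden):
            continue
        decoys.append(gene)
    return decoys


# ---------------------------------------------------------------------------
# expression simulation


@dataclass
class ExpressionSimSpec:
    """Specification for a synthetic FPKM-like expression matrix.

    ``n_samples`` is per condition.  ``dispersion`` is the standard
    deviation of natural-log expression.  ``planted_pairs`` are
    ``(gene_a, gene_b, target_pcc)`` triples: the target is the Pearson
    correlation of the expression values themselves (within a condition),
    achieved by planting a matched latent correlation under the log-normal
    marginals.  ``de_genes`` are ``(gene, log2fc, condition)`` triples
    shifting that gene's mean in the named condition.
    """

    genes: Sequence[str]
    n_samples: int = 8
    base_mean: float = 10.0
    dispersion: float = 0.5
    planted_pairs: Sequence[tuple[str, str, float]] = ()
    de_genes: Sequence[tuple[str, float, str]] = ()
    conditions: Sequence[str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be > 0")
        for a, b, r in self.planted_pairs:
            if abs(r) > 1:
                raise ValueError(f"|target_pcc| > 1 for pair ({a}, {b})")
        genes = set(self.genes)
        for a, b, _ in self.planted_pairs:
            if a not in genes or b not in genes:
                raise ValueError(f"planted pair ({a}, {b}) not in gene list")
        for g, _, cond in self.de_genes:
            if g not in genes:
                raise ValueError(f"DE gene {g} not in gene list")
            if cond not in self.conditions:
                raise ValueError(f"unknown condition {cond!r}")


def _latent_rho(target_pcc: float, sdlog: float) -> float:
    """Latent normal correlation giving `target_pcc` between the two
    log-normal variables (equal sdlog), by inverting the log-normal
    correlation formula."""
    v = math.expm1(sdlog**2)
    arg = 1.0 + target_pcc * v
    if arg <= 0:
        raise ValueError(
            f"target PCC {target_pcc} unreachable under dispersion {sdlog}"
        )
    rho = math.log(arg) / sdlog**2
    if abs(rho) > 1 + 1e-12:
        raise ValueError(
            f"target PCC {target_pcc} unreachable under dispersion {sdlog}"
        )
    return max(-1.0, min(1.0, rho))


def simulate_expression(
    spec: ExpressionSimSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an expression matrix (genes x samples) plus sample metadata.

    Values are log-normal with planted pairwise correlations (Gaussian
    copula) and condition-specific mean shifts for DE genes.  Raises
    ``ValueError`` if the requested correlation structure is not positive
    semi-definite.
    """
    rng = np.random.default_rng(seed)
    genes = list(spec.genes)
    g_idx = {g: i for i, g in enumerate(genes)}
    p = len(genes)
    corr = np.eye(p)
    for a, b, r in spec.planted_pairs:
        rho = _latent_rho(r, spec.dispersion)
        corr[g_idx[a], g_idx[b]] = rho
        corr[g_idx[b], g_idx[a]] = rho
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-8:
        raise ValueError("planted correlation structure is not positive semi-definite")
    chol = np.linalg.cholesky(corr + np.eye(p) * max(0.0, 1e-10 - eigvals.min()))

    shift = {cond: np.zeros(p) for cond in spec.conditions}
    for g, log2fc, cond in spec.de_genes:
        shift[cond][g_idx[g]] += log2fc * math.log(2.0)

    cols: list[str] = []
    meta_rows = []
    blocks = []
    for cond in spec.conditions:
        z = rng.standard_normal((spec.n_samples, p)) @ chol.T
        logx = math.log(spec.base_mean) + shift[cond] + spec.dispersion * z
        blocks.append(np.exp(logx).T)
        for i in range(spec.n_samples):
            cols.append(f"{cond}_s{i + 1}")
            meta_rows.append({"sample": f"{cond}_s{i + 1}", "condition": cond,
                              "time_point": i + 1})
    matrix = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return matrix, meta
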