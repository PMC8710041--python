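"""Interolog transfer: predicting VQ–WRKY partners from a reference
interactome via clade-based homology.

An edge between a query-species VQ gene and a same-species WRKY gene is
predicted whenever some reference interaction links a VQ homolog of the
first to a WRKY homolog of the second.  Connected components of the
resulting bipartite graph are classed one-to-one, one-to-many or
many-to-many.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "ReferenceInteractome",
    "InteractionEdge",
    "example_reference_interactome",
    "transfer_interactions",
    "classify_relationships",
    "export_network",
    "read_network",
]

#: minimal curated set of published Arabidopsis VQ-WRKY interactions
#: (SIB1/SIB2-WRKY33 defense module, VQ10-WRKY8, VQ20 pollen partners);
#: a testing fixture, not a full interactome
_EXAMPLE_AT_EDGES = frozenset(
    [
        ("AtVQ16", "AtWRKY33"),
        ("AtVQ23", "AtWRKY33"),
        ("AtVQ10", "AtWRKY8"),
        ("AtVQ20", "AtWRKY2"),
        ("AtVQ20", "AtWRKY34"),
    ]
)


def example_reference_interactome() -> "ReferenceInteractome":
    """Small bundled Arabidopsis VQ-WRKY interaction set for examples and
    tests; real analyses should supply a curated edge-list TSV."""
    return ReferenceInteractome(_EXAMPLE_AT_EDGES, provenance="bundled-example")


@dataclass
class ReferenceInteractome:
    """Known VQ–WRKY interaction pairs in a reference species."""

    edges: frozenset  # of (vq_gene, wrky_gene)
    provenance: str = ""

    def __post_init__(self) -> None:
        vqs = {a for a, _ in self.edges}
        wrkys = {b for _, b in self.edges}
        if vqs & wrkys:
            raise ValueError("reference VQ and WRKY gene ids overlap")
        if any(a == b for a, b in self.edges):
            raise ValueError("self-edges are not allowed")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "") -> "ReferenceInteractome":
        df = pd.read_csv(path, sep="\t")
        return cls(
            frozenset(zip(df["vq_gene"], df["wrky_gene"])),
            provenance or str(path),
        )


@dataclass
class InteractionEdge:
    """One predicted VQ–WRKY partner pair in a query species."""

    vq_gene: str
    wrky_gene: str
    species: str
    supporting_reference_edges: frozenset
    min_support: float | None = None


def transfer_interactions(
    vq_homologs: Mapping[str, set],
    wrky_homologs: Mapping[str, set],
    reference: ReferenceInteractome,
    species_of: Mapping[str, str],
    homolog_supports: Mapping[str, float] | None = None,
) -> list[InteractionEdge]:
    """Transfer reference interactions to query genes through homology.

    ``vq_homologs`` / ``wrky_homologs`` map query genes to reference-gene
    sets (as produced by :func:`famevol.phylo.call_homologs`, which already
    enforces the bootstrap-support threshold).  An edge (q_vq, q_wrky) is
    emitted iff some reference edge joins a homolog of each; both query
    genes must belong to the same species.  ``homolog_supports`` optionally
    carries the per-query-gene clade support used to record each edge's
    ``min_support``.
    """
    if not reference.edges:
        warnings.warn("empty reference interactome; no predictions possible")
        return []
    out: list[InteractionEdge] = []
    for q_vq in sorted(vq_homologs):
        h_vq = vq_homologs[q_vq]
        if not h_vq:
            continue
        for q_wrky in sorted(wrky_homologs):
            if species_of[q_vq] != species_of[q_wrky]:
                continue
            h_wrky = wrky_homologs[q_wrky]
            support = frozenset(
                (rv, rw)
                for rv, rw in reference.edges
                if rv in h_vq and rw in h_wrky
            )
            if not support:
                continue
            min_sup = None
            if homolog_supports is not None:
                sup_v = homolog_supports.get(q_vq)
                sup_w = homolog_supports.get(q_wrky)
                if sup_v is not None and sup_w is not None:
                    min_sup = min(sup_v, sup_w)
            out.append(
                InteractionEdge(q_vq, q_wrky, species_of[q_vq], support, min_sup)
            )
    return out


def classify_relationships(
    edges: Iterable[InteractionEdge],
) -> pd.DataFrame:
    """Class each connected component of the predicted bipartite graph.

    A component with one VQ and one WRKY gene is one-to-one; a single gene
    on one side facing several on the other is one-to-many; anything larger
    is many-to-many.  Returns per-species component counts.
    """
    by_species: dict[str, list[InteractionEdge]] = {}
    for e in edges:
        by_species.setdefault(e.species, []).append(e)
    rows = []
    for sp in sorted(by_species):
        g = nx.Graph()
        for e in by_species[sp]:
            g.add_node(("VQ", e.vq_gene))
            g.add_node(("WRKY", e.wrky_gene))
            g.add_edge(("VQ", e.vq_gene), ("WRKY", e.wrky_gene))
        counts = {"one_to_one": 0, "one_to_many": 0, "many_to_many": 0}
        for comp in nx.connected_components(g):
            n_vq = sum(1 for side, _ in comp if side == "VQ")
            n_wrky = len(comp) - n_vq
            if n_vq == 1 and n_wrky == 1:
                counts["one_to_one"] += 1
            elif n_vq == 1 or n_wrky == 1:
                counts["one_to_many"] += 1
            else:
                counts["many_to_many"] += 1
        rows.append({"species": sp, **counts})
    return pd.DataFrame(
        rows, columns=["species", "one_to_one", "one_to_many", "many_to_many"]
    )


def export_network(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    """Write a TSV edge list loadable by standard network viewers."""
    rows = [
        {
            "vq_gene": e.vq_gene,
            "wrky_gene": e.wrky_gene,
            "species": e.species,
            "min_support": "" if e.min_support is None else e.min_support,
            "supporting_reference_edges": ";".join(
                f"{a}-{b}" for a, b in sorted(e.supporting_reference_edges)
            ),
        }
        for e in edges
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "vq_gene",
            "wrky_gene",
            "species",
            "min_support",
            "supporting_reference_edges",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> list[InteractionEdge]:
    """Read back an edge list written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"min_support": float})
    out = []
    for _, r in df.iterrows():
        refs = r.get("supporting_reference_edges")
        support = frozenset(
            tuple(pair.rsplit("-", 1)) for pair in str(refs).split(";")
        ) if isinstance(refs, str) and refs else frozenset()
        min_sup = r.get("min_support")
        out.append(
            InteractionEdge(
                r["vq_gene"],
                r["wrky_gene"],
                r["species"],
                support,
                None if pd.isna(min_sup) else float(min_sup),
            )
        )
    return out
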