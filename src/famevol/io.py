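"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython; tables are TSV via pandas.  Simulated FASTA
headers encode ``species|gene_id`` and, behind a flag, the true clade id,
so identification can run blind or informed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .identify import GeneRecord
from .simulate import SimTruth, SimulatedGene

__all__ = [
    "write_family_fasta",
    "read_cds_fasta",
    "write_truth_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_clades_tsv",
    "read_clades_tsv",
    "write_pair_stats_tsv",
]


def write_family_fasta(
    genes: Sequence[SimulatedGene],
    path: str | Path,
    include_truth: bool = False,
) -> None:
    """Write simulated genes as CDS FASTA; headers are ``species|gene_id``
    plus ``|clade`` when truth is requested."""
    records = []
    for g in genes:
        header = f"{g.species}|{g.gene_id}"
        if include_truth:
            header += f"|c{g.clade_id:02d}"
        records.append(SeqRecord(Seq(g.cds), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_cds_fasta(path: str | Path, species: str | None = None) -> list[GeneRecord]:
    """Read a CDS FASTA into GeneRecords.

    Headers of the form ``species|gene_id[|clade]`` carry their species;
    otherwise ``species`` must be given.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) >= 2:
            sp, gid = parts[0], parts[1]
        else:
            if species is None:
                raise ValueError(
                    f"record {rec.id!r} has no species field and none was given"
                )
            sp, gid = species, rec.id
        out.append(GeneRecord(gene_id=gid, species=sp, cds=str(rec.seq)))
    return out


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    rows = [
        {
            "event": ev.kind,
            "species_branch": ev.species_branch,
            "clade_id": ev.clade_id,
            "ks_depth": ev.ks_depth,
        }
        for ev in truth.event_log
    ]
    pd.DataFrame(
        rows, columns=["event", "species_branch", "clade_id", "ks_depth"]
    ).to_csv(path, sep="\t", index=False)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_clades_tsv(partition, path: str | Path) -> None:
    rows = [
        {"gene_id": g, "clade_id": cid}
        for cid, genes in sorted(partition.clades.items())
        for g in sorted(genes)
    ]
    rows += [{"gene_id": g, "clade_id": "unassigned"} for g in sorted(partition.unassigned)]
    pd.DataFrame(rows, columns=["gene_id", "clade_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_clades_tsv(path: str | Path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set] = {}
    for _, r in df.iterrows():
        if r["clade_id"] == "unassigned":
            continue
        out.setdefault(r["clade_id"], set()).add(r["gene_id"])
    return out


def write_pair_stats_tsv(pairs: Iterable, path: str | Path) -> None:
    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "clade": p.clade_id,
            "class": p.pair_class,
            "Ka": "" if p.ka is None else p.ka,
            "Ks": "" if p.ks is None else p.ks,
            "omega": "" if p.omega is None else p.omega,
            "ks_valid": p.ks_valid,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "clade", "class", "Ka", "Ks", "omega", "ks_valid"],
    ).to_csv(path, sep="\t", index=False)
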