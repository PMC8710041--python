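"""Identification of VQ and WRKY family members from coding sequences.

Family membership is called from the translated CDS by two evidence
channels: a motif scan (configurable amino-acid regular expressions for the
VQ core ``FxxxVQxLTG`` and the WRKY signature ``WRKYG[QK]K``) and an
ungapped similarity search against bundled seed-domain sequences with a
Karlin–Altschul E-value gate.  When cross-verification is required both
channels must agree; otherwise the motif channel alone decides.  External
domain calls (e.g. from a profile-HMM scanner) can be supplied as a TSV and
override the built-in scan.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "GeneRecord",
    "IdentifyConfig",
    "first_transcript_filter",
    "scan_family",
    "identify_families",
    "family_census",
    "translate_cds",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# Karlin-Altschul parameters for ungapped BLOSUM62 scoring
_KA_LAMBDA = 0.318
_KA_K = 0.13

# Synthetic seed-domain sequences used by the similarity channel.  These are
# artificial constructs built around the two family signatures (they are not
# database records): a VQ-domain-like segment and a WRKY-domain-like segment.
VQ_SEED_DOMAIN = "SPKIRIVHIFAPEIIKTDVANFVTKVQELTGKPAAEERSGSKRRS"
WRKY_SEED_DOMAIN = "DGYNWRKYGQKQVKGSENPRSYYKCTHPNCPVKKKVERSLDGQITEIVYKGSHNH"


@dataclass
class GeneRecord:
    """One CDS with its species, family call and supporting evidence."""

    gene_id: str
    species: str
    cds: str
    protein: str = ""
    family: str = "none"  # "VQ" | "WRKY" | "none"
    evidence: set = field(default_factory=set)
    flagged: bool = False  # internal stop codon or untranslatable

    def __post_init__(self) -> None:
        if not self.protein and self.cds:
            self.protein, self.flagged = translate_cds(self.cds)


def translate_cds(cds: str) -> tuple[str, bool]:
    """Standard-code translation; returns (protein, has_internal_stop).

    Trailing incomplete codons are trimmed; a terminal stop is dropped.
    """
    from ._codons import translate_codon

    cds = cds.upper()
    usable = len(cds) - len(cds) % 3
    aas = [translate_codon(cds[i : i + 3]) for i in range(0, usable, 3)]
    if aas and aas[-1] == "*":
        aas = aas[:-1]
    protein = "".join(aas)
    return protein.replace("*", "*"), "*" in protein


@dataclass
class IdentifyConfig:
    """Patterns and thresholds of the identification stage.

    The default VQ pattern is the ``FxxxVQxLTG`` core with one degenerate
    position (the L); the WRKY pattern covers the canonical WRKYGQK
    heptapeptide and its common WRKYGKK variant.
    """

    vq_pattern: str = r"F...VQ..TG"
    wrky_pattern: str = r"WRKYG[QK]K"
    evalue_threshold: float = 1e-4
    require_cross_verification: bool = False

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")


def first_transcript_filter(
    records: Sequence[GeneRecord], delimiter: str = "."
) -> list[GeneRecord]:
    """Keep only the lowest-numbered transcript of each gene.

    Gene ids are expected to end in ``<gene><delimiter><number>``; records
    whose ids do not parse are kept unchanged (with a warning).  Gene order
    of first appearance is preserved.  The operation is idempotent.
    """
    pattern = re.compile(rf"^(?P<gene>.+){re.escape(delimiter)}(?P<t>\d+)$")
    # best[gene] = (transcript number, first-appearance position, record)
    best: dict[str, tuple[int, int, GeneRecord]] = {}
    passthrough: list[tuple[int, GeneRecord]] = []
    for pos, rec in enumerate(records):
        m = pattern.match(rec.gene_id)
        if m is None:
            warnings.warn(f"gene id {rec.gene_id!r} has no transcript suffix; kept")
            passthrough.append((pos, rec))
            continue
        gene, t = m.group("gene"), int(m.group("t"))
        if gene not in best:
            best[gene] = (t, pos, rec)
        elif t < best[gene][0]:
            best[gene] = (t, best[gene][1], rec)
    merged = passthrough + [(pos, rec) for _, pos, rec in best.values()]
    merged.sort(key=lambda x: x[0])
    return [rec for _, rec in merged]


def _best_ungapped_score(query: str, seed: str) -> float:
    """Best ungapped local alignment score (max over diagonals of the best
    contiguous segment) under BLOSUM62."""
    best = 0.0
    nq, ns = len(query), len(seed)
    for offset in range(-(ns - 1), nq):
        run = 0.0
        high = 0.0
        for j in range(ns):
            i = offset + j
            if i < 0 or i >= nq:
                continue
            try:
                s = _BLOSUM62[query[i], seed[j]]
            except (KeyError, IndexError):
                s = -4.0
            run = max(0.0, run + s)
            high = max(high, run)
        best = max(best, high)
    return best


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def scan_family(
    record: GeneRecord, cfg: IdentifyConfig | None = None
) -> GeneRecord:
    """Assign a family call and evidence channels to one record (in place).

    VQ if the VQ pattern matches the protein, WRKY if the WRKY pattern
    matches; a protein matching both is left unassigned as ambiguous.
    With ``require_cross_verification`` the similarity channel (ungapped
    alignment to the family seed domain, E-value <= threshold) must agree.
    Records with internal stop codons are flagged and never assigned.
    """
    cfg = cfg or IdentifyConfig()
    record.evidence = set()
    record.family = "none"
    if record.flagged or not record.protein:
        return record
    vq = re.search(cfg.vq_pattern, record.protein) is not None
    wrky = re.search(cfg.wrky_pattern, record.protein) is not None
    if vq == wrky:  # neither, or ambiguous both
        return record
    family = "VQ" if vq else "WRKY"
    record.evidence.add("motif_scan")
    seed = VQ_SEED_DOMAIN if family == "VQ" else WRKY_SEED_DOMAIN
    score = _best_ungapped_score(record.protein, seed)
    if _evalue(score, len(record.protein), len(seed)) <= cfg.evalue_threshold:
        record.evidence.add("similarity_search")
    if cfg.require_cross_verification and "similarity_search" not in record.evidence:
        record.evidence = set()
        return record
    record.family = family
    return record


def identify_families(
    records: Iterable[GeneRecord],
    cfg: IdentifyConfig | None = None,
    external_calls: pd.DataFrame | None = None,
) -> list[GeneRecord]:
    """Scan every record; optional external calls override the scan.

    ``external_calls`` needs columns ``gene_id``, ``family`` (and may carry
    a ``source`` column); listed genes take the external family with
    evidence ``similarity_search``.
    """
    override: dict[str, str] = {}
    if external_calls is not None:
        override = dict(zip(external_calls["gene_id"], external_calls["family"]))
    out = []
    for rec in records:
        if rec.gene_id in override:
            rec.family = override[rec.gene_id]
            rec.evidence = {"similarity_search"}
        else:
            scan_family(rec, cfg)
        out.append(rec)
    return out


def family_census(records: Iterable[GeneRecord]) -> pd.DataFrame:
    """Per-species gene counts and mean CDS lengths per family.

    Flagged records and records without a family call are excluded.
    Returns a tidy frame with columns species, family, n_genes,
    mean_cds_length, plus one total row per family.
    """
    rows = [
        {"species": r.species, "family": r.family, "cds_length": len(r.cds)}
        for r in records
        if r.family != "none" and not r.flagged
    ]
    if not rows:
        return pd.DataFrame(
            columns=["species", "family", "n_genes", "mean_cds_length"]
        )
    df = pd.DataFrame(rows)
    census = (
        df.groupby(["species", "family"], sort=True)
        .agg(n_genes=("cds_length", "size"), mean_cds_length=("cds_length", "mean"))
        .reset_index()
    )
    totals = (
        df.groupby("family", sort=True)
        .agg(n_genes=("cds_length", "size"), mean_cds_length=("cds_length", "mean"))
        .reset_index()
    )
    totals.insert(0, "species", "total")
    return pd.concat([census, totals], ignore_index=True)
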