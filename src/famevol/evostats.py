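"""Pairwise molecular-evolution statistics for gene families.

Implements Nei–Gojobori (1986) Ka/Ks with equal-weight minimal-pathway
counting and Jukes–Cantor correction, nucleotide diversity (Pi) with
pairwise deletion, Ks histogramming with a saturation cutoff, conversion of
Ks to duplication time via a per-generation mutation rate, duplication/loss
inference from clade partitions, and the Welch t contrasts used to compare
paralogs with orthologs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._codons import pathway_differences, syn_site_fraction
from .phylo import CladePartition, Node

__all__ = [
    "PairStats",
    "DiversityStats",
    "KsHistogram",
    "DatingParams",
    "DupLossReport",
    "nei_gojobori",
    "classify_pairs",
    "compute_pair_stats",
    "nucleotide_diversity",
    "ks_histogram",
    "estimate_duplication_time",
    "infer_dup_loss",
    "welch_t",
    "selection_summary",
]

_NT = frozenset("ACGT")


@dataclass
class PairStats:
    """Ka/Ks record for one within-clade gene pair."""

    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    clade_id: str
    pair_class: str  # "paralog" | "ortholog"
    ka: float | None = None
    ks: float | None = None
    omega: float | None = None
    ks_valid: bool = True


@dataclass
class DiversityStats:
    clade_id: str
    pi: float
    n_sequences: int
    n_sites_used: float


@dataclass
class KsHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def modal_bin(self) -> tuple[float, float]:
        k = int(np.argmax(self.counts))
        return (float(self.bin_edges[k]), float(self.bin_edges[k + 1]))


@dataclass
class DatingParams:
    """Ks-to-time conversion parameters.

    Defaults follow the peach calibration: 9.48e-9 point mutations per site
    per generation and 3 years per generation, with Ks > 1 treated as
    saturated and discarded.
    """

    mu: float = 9.48e-9
    generation_years: float = 3.0
    ks_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_years <= 0 or self.ks_cutoff <= 0:
            raise ValueError("all dating parameters must be positive")


@dataclass
class DuplicationTime:
    years: float
    mya: float

    @property
    def mya_display(self) -> float:
        return round(self.mya, 2)


@dataclass
class DupLossReport:
    """Per-species duplication/loss summary with per-clade breakdown."""

    per_species: pd.DataFrame  # species, genes_involved, duplication_events, loss_events
    per_clade: pd.DataFrame  # clade_id, species, n_genes, duplication_events, lost
    mode: str


# ---------------------------------------------------------------------------
# Nei-Gojobori


def _codon_ok(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(c in _NT for c in codon)
        and codon not in ("TAA", "TAG", "TGA")
    )


def nei_gojobori(row_a: str, row_b: str) -> tuple[float | None, float | None]:
    """Nei–Gojobori (1986) Ka and Ks for one codon-aligned pair.

    Codons containing gaps, ambiguity codes or stops in either sequence are
    dropped pairwise.  Synonymous/nonsynonymous sites are averaged over the
    two sequences; differences are averaged over all minimal mutational
    pathways with equal weights.  Each proportion is Jukes–Cantor corrected
    (d = -3/4 ln(1 - 4p/3)); a proportion at or beyond 3/4 leaves that rate
    undefined (``None``), flagging saturation.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    if len(row_a) % 3:
        raise ValueError("alignment length not divisible by 3")
    S = N = Sd = Nd = 0.0
    for k in range(0, len(row_a), 3):
        ca, cb = row_a[k : k + 3].upper(), row_b[k : k + 3].upper()
        if not (_codon_ok(ca) and _codon_ok(cb)):
            continue
        sa, sb = syn_site_fraction(ca), syn_site_fraction(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    if S <= 0 or N <= 0:
        return None, None

    def jc(p: float) -> float | None:
        if p >= 0.75:
            return None
        return -0.75 * math.log1p(-4.0 * p / 3.0)

    return jc(Nd / N), jc(Sd / S)


# ---------------------------------------------------------------------------
# pair enumeration and filling


def classify_pairs(
    partition: CladePartition, species_of: Mapping[str, str]
) -> list[PairStats]:
    """All unordered within-clade gene pairs, classed paralog/ortholog.

    Same-species pairs are paralogs, cross-species pairs orthologs;
    cross-clade pairs are never generated.
    """
    out: list[PairStats] = []
    for cid in sorted(partition.clades):
        genes = sorted(partition.clades[cid])
        for a, b in itertools.combinations(genes, 2):
            sa, sb = species_of[a], species_of[b]
            out.append(
                PairStats(
                    a, b, sa, sb, cid,
                    "paralog" if sa == sb else "ortholog",
                )
            )
    return out


def compute_pair_stats(
    pairs: Iterable[PairStats],
    alignment_rows: Mapping[str, str],
    ks_cutoff: float = 1.0,
) -> list[PairStats]:
    """Fill Ka, Ks, omega for enumerated pairs from aligned rows.

    Omega is reported missing (None) when Ks is 0 or undefined; pairs with
    Ks above the saturation cutoff are flagged ``ks_valid=False``.
    """
    out = []
    for p in pairs:
        ka, ks = nei_gojobori(alignment_rows[p.gene_a], alignment_rows[p.gene_b])
        p.ka, p.ks = ka, ks
        p.omega = (ka / ks) if (ka is not None and ks is not None and ks > 0) else None
        p.ks_valid = ks is not None and ks <= ks_cutoff
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# nucleotide diversity


def nucleotide_diversity(
    rows: Sequence[str], clade_id: str = ""
) -> DiversityStats:
    """Pi: mean pairwise differences per site with pairwise deletion.

    Sites where either sequence has a gap or ambiguity code are excluded
    per pair.  Raises if any pair shares no comparable sites.
    """
    n = len(rows)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.frombuffer("".join(r.upper() for r in rows).encode(), dtype=np.uint8)
    arr = arr.reshape(n, -1)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    total = 0.0
    shared_used = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            ns = int(mask.sum())
            if ns == 0:
                raise ValueError(f"no comparable sites for pair ({i}, {j})")
            total += float(((arr[i] != arr[j]) & mask).sum()) / ns
            shared_used.append(ns)
    n_pairs = n * (n - 1) // 2
    return DiversityStats(
        clade_id=clade_id,
        pi=total / n_pairs,
        n_sequences=n,
        n_sites_used=float(np.mean(shared_used)),
    )


# ---------------------------------------------------------------------------
# Ks histogram and dating


def ks_histogram(
    pairs: Iterable[PairStats],
    bin_width: float = 0.1,
    ks_range: tuple[float, float] = (0.0, 1.0),
) -> KsHistogram:
    """Histogram of Ks over valid pairs; bins are half-open [lo, lo+w) and
    the range maximum falls in the last bin.  Pairs flagged ``ks_valid=False``
    or with undefined Ks are excluded."""
    lo, hi = ks_range
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    if not math.isclose(edges[-1], hi):
        edges = np.append(edges, hi)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for p in pairs:
        if not p.ks_valid or p.ks is None:
            continue
        if p.ks < lo or p.ks > hi:
            continue
        if p.ks >= hi:
            k = len(counts) - 1
        else:
            k = int((p.ks - lo) // bin_width)
            k = min(k, len(counts) - 1)
        counts[k] += 1
    return KsHistogram(edges, counts, bin_width)


def estimate_duplication_time(
    ks: float, params: DatingParams | None = None
) -> DuplicationTime:
    """Convert a Ks value to a duplication time: T = Ks / (mu / g).

    With the peach calibration (mu = 9.48e-9/site/generation, g = 3 years)
    Ks = 0.02 dates to 6.33 MYA.  Ks above the saturation cutoff raises.
    """
    params = params or DatingParams()
    if ks < 0:
        raise ValueError("Ks must be >= 0")
    if ks > params.ks_cutoff:
        raise ValueError(
            f"Ks = {ks} exceeds the saturation cutoff {params.ks_cutoff}; "
            "saturated pairs are discarded from dating"
        )
    years = ks / (params.mu / params.generation_years)
    return DuplicationTime(years=years, mya=years / 1e6)


# ---------------------------------------------------------------------------
# duplication / loss inference


def _count_dup_nodes(
    node: Node, species_of: Mapping[str, str]
) -> tuple[dict[str, int], dict[str, set]]:
    """Topology-mode counting: a duplication event is an internal node whose
    child subtrees share a species; genes of that species below the node are
    involved."""
    events: dict[str, int] = {}
    involved: dict[str, set] = {}

    def species_below(n: Node) -> dict[str, set]:
        if n.is_leaf:
            return {species_of[n.name]: {n.name}}
        merged: dict[str, set] = {}
        child_sets = [species_below(c) for c in n.children]
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for sp in set(child_sets[i]) & set(child_sets[j]):
                    events[sp] = events.get(sp, 0) + 1
                    involved.setdefault(sp, set()).update(
                        child_sets[i][sp], child_sets[j][sp]
                    )
        for cs in child_sets:
            for sp, genes in cs.items():
                merged.setdefault(sp, set()).update(genes)
        return merged

    species_below(node)
    return events, involved


def infer_dup_loss(
    partition: CladePartition,
    species_of: Mapping[str, str],
    species: Sequence[str],
    clade_subtrees: Mapping[str, Node] | None = None,
    ancestral_copies_per_clade: int = 1,
) -> DupLossReport:
    """Duplication and loss events per species from a clade partition.

    With ``clade_subtrees`` (gene-tree subtree per clade) duplications are
    counted topologically: each internal node whose child subtrees share a
    species is one event for that species.  Without subtrees the count mode
    applies: a species with n >= 2 copies in a clade has n - 1 events with
    all n genes involved (relative to one ancestral copy per clade).  A
    species absent from a clade counts one loss, interpretable because the
    clade already satisfies the partition criteria.
    """
    present = {sp for g, sp in species_of.items()}
    for sp in species:
        if sp not in present:
            warnings.warn(f"species {sp!r} has no genes in any clade")
    mode = "topology" if clade_subtrees else "count"
    clade_rows = []
    for cid in sorted(partition.clades):
        genes = partition.clades[cid]
        by_sp: dict[str, list[str]] = {sp: [] for sp in species}
        for g in genes:
            if species_of[g] in by_sp:
                by_sp[species_of[g]].append(g)
        if mode == "topology" and cid in clade_subtrees:
            ev, inv = _count_dup_nodes(clade_subtrees[cid], species_of)
        else:
            ev = {
                sp: max(len(gs) - ancestral_copies_per_clade, 0)
                for sp, gs in by_sp.items()
            }
            inv = {
                sp: set(gs) if len(gs) > ancestral_copies_per_clade else set()
                for sp, gs in by_sp.items()
            }
        for sp in species:
            clade_rows.append(
                {
                    "clade_id": cid,
                    "species": sp,
                    "n_genes": len(by_sp[sp]),
                    "duplication_events": ev.get(sp, 0),
                    "genes_involved": len(inv.get(sp, set())),
                    "lost": len(by_sp[sp]) == 0,
                }
            )
    per_clade = pd.DataFrame(clade_rows)
    if per_clade.empty:
        per_species = pd.DataFrame(
            columns=["species", "genes_involved", "duplication_events", "loss_events"]
        )
        return DupLossReport(per_species, per_clade, mode)
    per_species = (
        per_clade.groupby("species", sort=False)
        .agg(
            genes_involved=("genes_involved", "sum"),
            duplication_events=("duplication_events", "sum"),
            loss_events=("lost", "sum"),
        )
        .reindex(species)
        .reset_index()
    )
    return DupLossReport(per_species, per_clade, mode)


# ---------------------------------------------------------------------------
# statistics


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch unequal-variance t test: (t, Welch–Satterthwaite df, two-sided p).

    Two groups with zero variance and equal means give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return math.inf * math.copysign(1, a.mean() - b.mean()), float(
            len(a) + len(b) - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def selection_summary(
    pairs: Iterable[PairStats], by: str = "pair_class"
) -> pd.DataFrame:
    """Fractions of pairs under purifying (omega < 1) and positive
    (omega > 1) selection, per group and overall.

    Pairs with undefined omega are counted but excluded from percentage
    denominators.
    """
    rows = []
    for p in pairs:
        rows.append({"group": getattr(p, by), "omega": p.omega})
    df = pd.DataFrame(rows)
    out = []
    groups = [("all", df)] + [(g, sub) for g, sub in df.groupby("group")]
    for name, sub in groups:
        defined = sub["omega"].dropna()
        n_def = len(defined)
        n_pur = int((defined < 1).sum())
        n_pos = int((defined > 1).sum())
        out.append(
            {
                "group": name,
                "n_pairs": len(sub),
                "n_defined": n_def,
                "n_purifying": n_pur,
                "n_positive": n_pos,
                "pct_purifying": 100.0 * n_pur / n_def if n_def else math.nan,
                "pct_positive": 100.0 * n_pos / n_def if n_def else math.nan,
            }
        )
    return pd.DataFrame(out)
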