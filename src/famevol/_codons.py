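"""Codon-level bookkeeping shared by the simulator and the Ka/Ks estimator.

Everything here is derived once from the standard genetic code: the sense
codons, single-nucleotide neighbourhoods, per-position synonymous site
fractions (Nei–Gojobori counting), and minimal mutational pathways between
codon pairs.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

# preferred codon per amino acid (alphabetically first), for motif embedding
AA_TO_CODON: dict[str, str] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODON.setdefault(CODON_TO_AA[_codon], _codon)


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def single_nt_neighbors(codon: str) -> list[tuple[str, int, bool]]:
    """All sense codons one nucleotide away.

    Returns (neighbor, position, is_synonymous) triples; mutations to stop
    codons are omitted.
    """
    out = []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            out.append((alt, pos, CODON_TO_AA[alt] == aa))
    return out


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Nei–Gojobori synonymous site count s for one codon (0 <= s <= 3).

    At each position the fraction of the three possible changes that are
    synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in CODON_TO_AA and CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons.

    Counts are averaged over all minimal mutational pathways (orderings of
    the differing positions).  Pathways passing through a stop codon are
    excluded unless every pathway does.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                nd += 1.0
            elif current in STOP_CODONS:
                # leaving a stop codon on a blocked path: nonsynonymous
                nd += 1.0
            elif CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        paths.append((sd, nd, blocked))
    clean = [(s, n) for s, n, b in paths if not b]
    if not clean:
        clean = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


def translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA.get(codon, "X")
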