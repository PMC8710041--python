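# famevol

Comparative gene-family evolution analysis, modelled on the study design
used for plant transcription-factor families such as the VQ regulators and
their WRKY partners: identify family members in several closely related
species plus an outgroup, reconstruct their phylogeny, read off
duplication and loss history, estimate selective pressure and duplication
ages, transfer protein–protein interactions from a reference species, and
correlate the expression of predicted partners.

It is aimed at researchers who want a tested, reproducible version of this
classic pipeline — and, crucially, a way to validate every stage without
external genome downloads: a built-in simulator generates multi-species
families with full ground truth (event logs, true clade assignments, true
pairwise synonymous distances, planted expression correlations).

## What it computes

- **Identification** (`famevol.identify`): family calls from CDS via a
  motif scan (VQ core `FxxxVQxLTG`, WRKY signature `WRKYG[QK]K`) with an
  optional similarity cross-verification channel gated at E ≤ 10⁻⁴, a
  first-transcript filter, and a per-species census of counts and mean CDS
  lengths.
- **Phylogenetics** (`famevol.phylo`): protein-guided codon alignment
  (progressive BLOSUM62 profile alignment, back-translated so that
  ungapping recovers each input CDS exactly); neighbor-joining trees on
  p-distances with pairwise deletion and bootstrap supports from site
  resampling; partitioning into clades that contain ≥ 1 outgroup gene and
  genes from ≥ 5 ingroup species (each accepted clade = one ancestral
  copy); clade-based homolog calling at bootstrap support ≥ 50.
- **Molecular evolution** (`famevol.evostats`): Nei–Gojobori (1986) Ka and
  Ks with equal-weight minimal-pathway counting and Jukes–Cantor
  correction,

  d = −(3/4)·ln(1 − (4/3)p),

  with Ks > 1 discarded as saturated; nucleotide diversity
  π (mean pairwise differences per site, pairwise deletion); paralog /
  ortholog classification of within-clade pairs; Ks histograms;
  duplication dating T = Ks / (μ/g) with the peach calibration
  μ = 9.48×10⁻⁹ mutations·site⁻¹·generation⁻¹ and g = 3 years;
  duplication/loss counting per species; Welch t contrasts.
- **Interaction transfer** (`famevol.network`): interolog mapping — an
  edge is predicted between a query VQ and a same-species WRKY gene when
  homologs of each interact in the reference species — plus one-to-one /
  one-to-many / many-to-many component classification and Cytoscape-ready
  edge-list export.
- **Expression** (`famevol.expression`): differential-expression filtering
  (|log₂FC| ≥ 2 and BH-adjusted p < 0.05), four-way developmental
  stage-pattern classification, and Pearson correlations of predicted
  partner pairs with 0.05 / 0.01 significance stars.
- **Simulation** (`famevol.simulate`): birth–death gene families in
  Ks-time along a species tree (with an optional recent-duplication
  burst), a codon evolver with tunable ω = Ka/Ks, and a Gaussian-copula
  expression generator with planted pairwise correlations and fold
  changes.

## Worked example

Simulate a five-copy family over the bundled seven-species tree (six
ingroup species, one outgroup) with a burst of duplications within
Ks 0.005 of the present, then run the pipeline end to end:

```python
from famevol import simulate, phylo, evostats

tree = simulate.default_species_tree()
cfg = simulate.SimConfig(n_ancestral_copies=5, omega=0.2, codon_length=150,
                         recent_burst=(0.005, 60.0), seed=1)
genes, truth = simulate.simulate_dataset(tree, cfg)

aln = phylo.CodonAlignment.from_equal_length_cds(genes)
nj = phylo.nj_tree(aln, n_bootstrap=100, seed=1)
species_of = {g.gene_id: g.species for g in genes}
part = phylo.partition_clades(nj, species_of, outgroup="Fves",
                              min_ingroup_species=5)

rows = dict(zip(aln.gene_ids, aln.rows))
pairs = evostats.compute_pair_stats(evostats.classify_pairs(part, species_of), rows)
paralogs = [p for p in pairs if p.pair_class == "paralog" and p.ks is not None]
hist = evostats.ks_histogram(paralogs, bin_width=0.01, ks_range=(0.0, 0.1))
print("clades recovered:", len(part.clades))
print("modal Ks bin:", hist.modal_bin)
print("dates to", evostats.estimate_duplication_time(hist.modal_bin[1]).mya_display, "MYA")
```

This prints:

```
clades recovered: 5
modal Ks bin: (0.0, 0.01)
dates to 3.16 MYA
```

The five planted ancestral copies are recovered as exactly five clades;
the paralog Ks distribution peaks in the [0, 0.01) bin, reflecting the
planted burst, and the upper edge of that bin converts to 3.16 million
years under the peach mutation-rate calibration. On the same run,
`evostats.selection_summary(pairs)` reports 99.51 % of pairs with
Ka/Ks < 1 (the ω = 0.2 purifying regime), and
`evostats.infer_dup_loss(part, species_of, tree.species)` returns
per-species duplication-event counts that match the simulator's event log
exactly.

A command-line interface mirrors the library
(`famevol simulate family`, `famevol identify`, `famevol phylo
align|tree|clades|homologs`, `famevol evostats date --ks 0.02`,
`famevol network transfer`, `famevol expr de|pcc`).

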