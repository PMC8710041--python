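# Methods

This note documents the models, numerical choices and limitations behind
`famevol`. It is written for users who need to know exactly what each
stage computes and what the simulator-based validation does and does not
demonstrate.

## The family model

The package treats a gene family in a set of closely related species plus
one outgroup as descended from a fixed number of ancestral copies present
in the common ancestor. Each ancestral copy corresponds to one *clade* of
the gene tree, operationally defined by two criteria: the clade contains
at least one outgroup gene, and genes from at least `min_ingroup_species`
(default 5) distinct ingroup species. Within a clade, same-species pairs
are paralogs and cross-species pairs orthologs; pairs across clades are
never formed, since they coalesce before the ancestor of interest.

## Simulator

**Birth–death in Ks-time.** The species tree's branch lengths are expected
synonymous substitutions per synonymous site, so Ks doubles as the clock
and "recent duplication" means small Ks depth. Along every branch each
gene lineage duplicates at rate `birth_rate` and is lost at rate
`death_rate` (events per lineage per unit Ks); at speciation nodes every
surviving lineage enters both child branches. An optional
`recent_burst = (ks_offset, extra_rate)` adds duplication rate within
`ks_offset` of the present on terminal branches only. This terminal-branch
restriction makes per-species event attribution unambiguous — an internal-
branch duplication is inherited by every descendant species and cannot be
assigned to one of them — and is the regime used by the recovery tests.
The bundled default tree has six ingroup species at crown depth ≈ 0.07 Ks
and an outgroup at 0.26 Ks, consistent with converting a crown age of
roughly 36–44 Myr at the peach mutation rate.

Ground truth records every event (kind, branch, clade, Ks depth), the
clade of every surviving gene, and true pairwise Ks as path lengths in the
pruned gene trees.

**Codon evolution.** Each codon evolves independently by a continuous-time
process over the 61 sense codons. Single-nucleotide changes occur at rate
1/3 per synonymous alternative, so one unit of branch length equals one
expected synonymous substitution per Nei–Gojobori synonymous site; each
nonsynonymous alternative gets rate ω/3 multiplied by a per-codon factor
(the ratio of all nonsynonymous changes, stops included, to sense-codon
nonsynonymous changes). The factor compensates for the fact that the
process never substitutes into stop codons while NG site counting treats
stop-bound changes as nonsynonymous sites; without it the realized Ka/Ks
sits ~5 % below ω. Round trips confirm the calibration: at true Ks = 0.3
and 500 codons the mean NG estimate is within ~2 % of the truth, and ω = 1
simulations give mean estimated Ka/Ks ≈ 0.99.

Every simulated protein begins with Met followed by the family motif
(default `FVTKVQELTG`); those codons are frozen so the identification
stage can be validated against perfect ground truth. The ~10 frozen codons
out of ≥ 120 introduce a slight downward bias in absolute divergence but
cancel in the Ka/Ks ratio. Clade root sequences are drawn independently,
so inter-clade divergence is effectively saturated ("deep separation")
while intra-clade divergence follows the species tree — the regime of a
family descended from long-separated ancestral copies. Decoy sequences
(random codons guaranteed free of both family motifs) serve as negative
controls.

**Expression.** FPKM-like values are log-normal: log x = log(base_mean) +
condition shift + dispersion·z, with `dispersion` the SD of natural-log
expression (default 0.5) and z drawn from a Gaussian copula. A planted
pair's target Pearson correlation applies to the expression values
themselves; the latent correlation is obtained by inverting the log-normal
correlation formula ρ_latent = ln(1 + r(e^{s²}−1))/s², which is exact for
equal dispersions. Unreachable targets and non-positive-semi-definite
correlation structures raise errors. DE genes shift the named condition's
log-mean by log2fc·ln 2, so realized mean ratios equal 2^log2fc.
Correlations are planted within conditions; pooling across conditions with
DE shifts would distort them. Fisher-z coverage of planted correlations is
assessed on the log scale, where the copula is exactly Gaussian; on the
raw scale log-normal tails make the z-interval slightly liberal (~90 %
empirical coverage at r = 0.95, n = 8).

## Identification

Profile-HMM domain scanning is replaced by configurable amino-acid regular
expressions (defaults: VQ core `F...VQ..TG`, WRKY `WRKYG[QK]K` covering
the GQK and GKK variants). A second evidence channel computes the best
ungapped BLOSUM62 segment score against a bundled seed-domain sequence and
converts it to a Karlin–Altschul E-value (ungapped parameters λ = 0.318,
K = 0.13) gated at E ≤ 10⁻⁴; with `require_cross_verification` both
channels must agree, otherwise the motif channel decides. The seed
sequences are synthetic constructs around the family signatures, not
database records. External domain calls can be imported as a TSV and
override the scan. Records with internal stop codons are flagged and
excluded from family counts. The first-transcript filter keeps the
lowest-numbered transcript per gene under a configurable
`geneID.N` dialect and is idempotent.

## Alignment and trees

Codon alignment is protein-guided: a UPGMA guide tree over pairwise
identity distances (pairwise global alignments, BLOSUM62, gap open −10,
extend −0.5), progressive profile–profile alignment with average-of-pairs
BLOSUM62 scoring and affine gaps (Gotoh), then back-translation in whole
codons. Trailing nucleotides beyond the translated region (terminal stop
codons, incomplete codons) are re-appended and gap-padded so that
ungapping any row reproduces its input CDS byte-for-byte. For simulator
output, which contains no indels, `CodonAlignment.from_equal_length_cds`
constructs the (trivial) alignment directly; the progressive aligner is
exercised on indel-bearing cases in its own tests.

Distances are p-distances with pairwise deletion of non-ACGT sites
(Jukes–Cantor correction behind a flag); a pair with no shared ungapped
sites is an error naming the pair. Trees are Saitou–Nei neighbor joining;
equal Q values break toward the lexicographically smallest pair of cluster
labels (a cluster is labelled by its smallest leaf name), making the
procedure deterministic. Bootstrap supports resample alignment columns
with replacement and report the percentage of replicate trees containing
each internal bipartition; `n_bootstrap=0` skips supports. NJ on an
additive matrix provably recovers the generating topology; the tests check
this against exhaustive least-squares search over all unrooted topologies
on 4 and 5 taxa.

**Rooting.** In a gene-family tree the outgroup species' genes appear
inside every clade, so "root on the outgroup edge" is only well defined
when the outgroup genes form one side of an edge; in that case the root
goes at that edge's midpoint. Otherwise the tree is midpoint-rooted on its
longest leaf-to-leaf path — with deeply separated clades the diameter runs
between two clades, so the root lands between clades and leaves them
intact.

**Clade partitioning.** The search is deepest-first: a subtree is accepted
as a clade iff it satisfies both criteria and no split below it yields two
or more disjoint qualifying subtrees. This returns the finest partition
consistent with the criteria (preferring more, smaller clades), which
matches reading each clade as a distinct ancestral copy; leaves covered by
no accepted clade are reported unassigned. How nested qualifying clades
should be resolved is genuinely open in the underlying design; this rule
is the package's documented choice.

**Homolog calling.** For each query gene, the reference genes in its
smallest enclosing clade whose subtending node has bootstrap support at or
above the threshold (default 50) and which contains at least one
reference gene. Nodes without a support value — including the root — never
qualify, so a gene with no supported reference-containing ancestor gets an
empty homolog set rather than inheriting the whole reference set.

## Molecular-evolution statistics

**Nei–Gojobori.** Synonymous sites per codon are the per-position
fractions of the three possible changes that are synonymous, with changes
to stop codons counted as nonsynonymous; site totals are averaged over the
two sequences. Differences are averaged over all minimal mutational
pathways with equal weights; pathways through stop codons are excluded
unless every pathway is blocked (the classic convention — note that
Biopython's NG86 averages stop-traversing pathways in, which the
cross-check test masks out). Codons with gaps or ambiguity in either
sequence are dropped pairwise. Each proportion is Jukes–Cantor corrected;
p ≥ 3/4 leaves that rate undefined (saturation) and the pair is excluded
downstream. ω is reported missing (never infinite) when Ks = 0 or
undefined, and such pairs are excluded from selection-summary
denominators. The saturation discard applies to Ks only (Ks > 1 by
default); Ka is not independently filtered.

**Pi** is the mean over unordered pairs of differences per pairwise-
deletion site; it equals a naive double-loop implementation exactly.

**Ks histograms** use half-open bins [lo, lo+w) with the range maximum
assigned to the last bin; invalid (saturated) pairs are excluded. Both the
0.1 and 0.01 bin widths used for coarse and fine views are parameters, as
is the range — the fine-scale peak location is sensitive to this choice,
so it is exposed rather than fixed.

**Dating** converts Ks to years as T = Ks/(μ/g), defaulting to the peach
calibration μ = 9.48×10⁻⁹ per site per generation and g = 3 years; display
values are rounded to two decimals in MYA (Ks 0.02 → 6.33 MYA,
0.01 → 3.16 MYA). T is linear in Ks; Ks above the saturation cutoff is
rejected.

**Duplication/loss.** Two counting modes. Topology mode (when per-clade
gene subtrees are supplied): each internal node whose child subtrees share
a species is one duplication event for that species, and that species'
genes below such nodes are "involved". Count mode (fallback): a species
with n ≥ 2 copies in a clade has n − 1 events involving all n genes. A
species absent from a clade counts one loss — interpretable as loss rather
than clade nonexistence precisely because accepted clades already satisfy
the outgroup and species-breadth criteria. The two modes agree when all
duplications are terminal-branch; they differ when shared internal
duplications inflate per-species copy numbers.

**Welch t** uses the unequal-variance statistic with Welch–Satterthwaite
degrees of freedom; two zero-variance groups with equal means return
p = 1. Type-I error is calibrated to 5 % ± 0.5 % over 10,000 null
replicates in the test suite.

## Interaction transfer and expression

Interolog transfer emits an edge (q_vq, q_wrky) iff some reference edge
joins a homolog of each; both query genes must share a species. All
supported edges are emitted — when a query gene has several reference
homologs with conflicting evidence there is no precedence rule, so none is
invented. Each edge records its supporting reference edges and the smaller
of the two homology-clade supports, enabling re-filtering at thresholds
other than 50 without recomputing trees. Components of the bipartite graph
are classed 1 VQ + 1 WRKY → one-to-one; a single gene on one side →
one-to-many; otherwise many-to-many.

DE calling is threshold-based: log₂FC from condition means with a
pseudocount of 0.01 FPKM, per-gene Welch t on log₂(x + ε) when both
conditions have replicates, BH adjustment across all genes in the supplied
matrix (not only family members), and DE iff |log₂FC| ≥ 2 and adjusted
p < 0.05 (`fdr_max ≥ 1` disables the p filter, so fully permissive
thresholds mark every gene). With single samples, fold change alone
decides and p-values are reported missing. Stage patterns operationalize a
qualitative four-way description: stage means on the log₂ scale over three
developmental windows (defaults 3–30, 31–45, 52–94 days after full bloom);
spread < τ (default 1 log₂ unit) → uniform; else early-peak if stage I has
the largest mean and the first time point is the row maximum; late-peak if
the row maximum falls in the final third of stage III; mid-peak otherwise;
ties break toward the earlier pattern. τ and the windows are
artifact-defined parameters, not biological constants. Pair correlations
are sample Pearson r over matched samples with two-sided t-based p
(n − 2 df) and 0.05/0.01 stars; zero-variance profiles give NA.

## Validation scope and problem sizes

The test suite validates against simulator ground truth and independent
oracles, at sizes chosen to keep the default run fast: recovery tests use
5 ancestral copies, 6 + 1 species, 120–500 codons, 100 replicates for
event-count recovery, 100–500 seeds for statistical calibration, and
10,000 replicates for Welch type-I error. Passing these tests shows the
pipeline is internally correct and well calibrated under the simulator's
assumptions — independent codon sites, uniform codon frequencies, a single
ω, no indels within families, no gene conversion, no rate variation, and
log-normal expression. Real data violate several of these (alignment
uncertainty, codon bias, rate heterogeneity, segmental duplications), so
recovery rates on real genomes will be lower than the simulator's
near-perfect figures; the simulator establishes correctness, not
field accuracy.

## Known limitations

- Motif regular expressions are a deliberate stand-in for profile-HMM
  scanning; diverged family members without the literal motif are missed
  unless external calls are imported.
- NJ with p-distances inherits the usual distance-method limitations at
  high divergence; inter-clade branch lengths near saturation are not
  meaningful (clade membership, not inter-clade topology, is what the
  pipeline consumes).
- Midpoint rooting can misplace the root if one clade is far more
  divergent than the rest.
- Loss counting depends on the clade criteria: a clade absent from the
  partition (e.g. missing outgroup gene) contributes no loss events.
- Whole-genome duplication and gene-structure (intron) evolution are out
  of scope; only CDS is modelled. The loss model is a free knob: no
  empirical loss rate is implied.
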