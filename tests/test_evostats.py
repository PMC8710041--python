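"""Ka/Ks, Pi, Ks histograms, duplication dating, dup/loss, Welch t."""

import itertools
import math

import numpy as np
import pytest

from famevol import evostats, phylo, simulate
from famevol.evostats import (
    DatingParams,
    PairStats,
    classify_pairs,
    compute_pair_stats,
    estimate_duplication_time,
    infer_dup_loss,
    ks_histogram,
    nei_gojobori,
    nucleotide_diversity,
    selection_summary,
    welch_t,
)

from oracles import naive_pi, ng_pathway_counts, ng_syn_sites


class TestNeiGojobori:
    def test_identical_sequences(self):
        ka, ks = nei_gojobori("ATGGCTAAA", "ATGGCTAAA")
        assert ka == 0.0 and ks == 0.0

    def test_single_synonymous_difference_hand_value(self):
        """One Phe TTT->TTC change in a 10-codon run: S = 10/3 sites,
        Sd = 1, ps = 0.3, Ks = -3/4 ln(1 - 0.4)."""
        a = "TTT" * 10
        b = "TTT" * 9 + "TTC"
        ka, ks = nei_gojobori(a, b)
        assert ka == 0.0
        assert ks == pytest.approx(-0.75 * math.log(1 - 0.4))

    def test_symmetry(self, burst_dataset):
        genes, _, _ = burst_dataset
        a, b = genes[0].cds, genes[1].cds
        assert nei_gojobori(a, b) == nei_gojobori(b, a)

    def test_pathway_counts_match_exhaustive_oracle(self):
        """Difference counting agrees with independent pathway enumeration
        for every pair of sense codons."""
        from famevol._codons import SENSE_CODONS, pathway_differences, syn_site_fraction

        for ca in SENSE_CODONS:
            assert syn_site_fraction(ca) == pytest.approx(ng_syn_sites(ca))
            for cb in SENSE_CODONS:
                assert pathway_differences(ca, cb) == pytest.approx(
                    ng_pathway_counts(ca, cb)
                )

    def test_matches_independent_ng86_implementation(self):
        """Full Ka/Ks agrees with Biopython's NG86 on evolved pairs.

        Biopython averages over all minimal pathways including those
        passing through stop codons, whereas the classic counting excludes
        them, so codon pairs with a stop-traversing pathway are masked out
        before the comparison.
        """
        import itertools
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        from famevol._codons import STOP_CODONS

        def stop_free(ca, cb):
            diff = [i for i in range(3) if ca[i] != cb[i]]
            for order in itertools.permutations(diff):
                cur = ca
                for pos in order:
                    cur = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if cur in STOP_CODONS:
                        return False
            return True

        root = simulate.GeneNode(0.0)
        x, y = simulate.GeneNode(0.1), simulate.GeneNode(0.1)
        x.gene_id, y.gene_id = "x", "y"
        root.children = [x, y]
        cfg = simulate.SimConfig(n_ancestral_copies=1, omega=0.4, codon_length=200)
        for seed in range(5):
            seqs = simulate.evolve_codons(root, cfg, seed=seed)
            kept = [
                (seqs["x"][k : k + 3], seqs["y"][k : k + 3])
                for k in range(0, len(seqs["x"]), 3)
                if stop_free(seqs["x"][k : k + 3], seqs["y"][k : k + 3])
            ]
            a = "".join(ca for ca, _ in kept)
            b = "".join(cb for _, cb in kept)
            ka, ks = nei_gojobori(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert ka == pytest.approx(dn, abs=1e-9)
            assert ks == pytest.approx(ds, abs=1e-9)

    def test_gapped_codons_dropped_pairwise(self):
        ka, ks = nei_gojobori("ATG---TTT", "ATGGCTTTT")
        ka2, ks2 = nei_gojobori("ATGTTT", "ATGTTT")
        assert (ka, ks) == (ka2, ks2)

    def test_saturation_returns_none(self):
        # every third position differs synonymously -> ps far beyond 3/4
        a = "TTT" * 3
        b = "TTC" * 3
        ka, ks = nei_gojobori(a, b)
        assert ks is None


class TestClassifyPairs:
    def test_mixed_clade(self):
        part = phylo.CladePartition(
            {"C1": frozenset({"A1", "A2", "B1"})}, {}, frozenset()
        )
        pairs = classify_pairs(part, {"A1": "A", "A2": "A", "B1": "B"})
        classes = {(p.gene_a, p.gene_b): p.pair_class for p in pairs}
        assert classes == {
            ("A1", "A2"): "paralog",
            ("A1", "B1"): "ortholog",
            ("A2", "B1"): "ortholog",
        }

    def test_singleton_clade_no_pairs(self):
        part = phylo.CladePartition({"C1": frozenset({"A1"})}, {}, frozenset())
        assert classify_pairs(part, {"A1": "A"}) == []

    def test_same_species_pair_count(self):
        n = 7
        genes = {f"g{i}" for i in range(n)}
        part = phylo.CladePartition({"C1": frozenset(genes)}, {}, frozenset())
        pairs = classify_pairs(part, {g: "sp" for g in genes})
        assert len(pairs) == n * (n - 1) // 2
        assert all(p.pair_class == "paralog" for p in pairs)


class TestNucleotideDiversity:
    def test_two_sequences(self):
        stats = nucleotide_diversity(["ACGTACGTAC", "ACGTACGTAT"])
        assert stats.pi == pytest.approx(0.1)

    def test_identical(self):
        assert nucleotide_diversity(["ACGT", "ACGT", "ACGT"]).pi == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            "".join(rng.choice(list("ACGT-"), size=60, p=[0.23] * 4 + [0.08]))
            for _ in range(5)
        ]
        stats = nucleotide_diversity(rows)
        assert stats.pi == naive_pi(rows)

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(["AC--", "--GT"])


def _pairs_with_ks(values, valid=None):
    valid = valid or [True] * len(values)
    return [
        PairStats("a", "b", "x", "x", "C1", "paralog", ks=v, ks_valid=f)
        for v, f in zip(values, valid)
    ]


class TestKsHistogram:
    def test_binning(self):
        hist = ks_histogram(_pairs_with_ks([0.005, 0.015, 0.95]), bin_width=0.1)
        assert hist.counts[0] == 2
        assert hist.counts[-1] == 1
        assert hist.counts.sum() == 3

    def test_range_max_in_last_bin(self):
        hist = ks_histogram(_pairs_with_ks([1.0]), bin_width=0.1)
        assert hist.counts[-1] == 1

    def test_empty_and_invalid_excluded(self):
        hist = ks_histogram(_pairs_with_ks([], []))
        assert hist.counts.sum() == 0
        hist = ks_histogram(_pairs_with_ks([0.5, 0.5], [True, False]))
        assert hist.counts.sum() == 1

    def test_burst_mode_recovered(self, burst_dataset):
        """A duplication burst within Ks 0.005 of the present puts the
        histogram mode in the first fine bin."""
        genes, truth, _ = burst_dataset
        aln = phylo.CodonAlignment.from_equal_length_cds(genes)
        rows = dict(zip(aln.gene_ids, aln.rows))
        part = phylo.CladePartition(
            {
                f"C{c}": frozenset(
                    g.gene_id for g in genes if g.clade_id == c
                )
                for c in range(1, 6)
            },
            {},
            frozenset(),
        )
        species_of = {g.gene_id: g.species for g in genes}
        pairs = [
            p
            for p in classify_pairs(part, species_of)
            if p.pair_class == "paralog"
        ]
        pairs = compute_pair_stats(pairs, rows)
        hist = ks_histogram(pairs, bin_width=0.01, ks_range=(0.0, 0.1))
        assert hist.modal_bin in [(0.0, 0.01), (0.01, 0.02)]


class TestDuplicationDating:
    def test_zero(self):
        assert estimate_duplication_time(0.0).years == 0.0

    def test_peach_calibration_display_values(self):
        assert estimate_duplication_time(0.02).mya_display == 6.33
        assert estimate_duplication_time(0.01).mya_display == 3.16

    def test_linearity(self):
        t1 = estimate_duplication_time(0.2).years
        t2 = estimate_duplication_time(0.4).years
        assert t2 == pytest.approx(2 * t1)

    def test_saturated_ks_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            estimate_duplication_time(1.2)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DatingParams(mu=-1)


class TestDupLoss:
    @staticmethod
    def _partition(clades):
        return phylo.CladePartition(
            {cid: frozenset(genes) for cid, genes in clades.items()},
            {},
            frozenset(),
        )

    def test_count_mode_n_minus_one(self):
        part = self._partition({"C1": {"A_1", "A_2", "A_3", "B_1"}})
        sp = {g: g.split("_")[0] for g in ["A_1", "A_2", "A_3", "B_1"]}
        rep = infer_dup_loss(part, sp, ["A", "B"])
        row = rep.per_species.set_index("species")
        assert row.loc["A", "duplication_events"] == 2
        assert row.loc["A", "genes_involved"] == 3
        assert row.loc["B", "duplication_events"] == 0

    def test_absent_species_counts_loss(self):
        part = self._partition({"C1": {"A_1", "B_1"}})
        sp = {"A_1": "A", "B_1": "B"}
        with pytest.warns(UserWarning, match="'C'"):
            rep = infer_dup_loss(part, sp, ["A", "B", "C"])
        row = rep.per_species.set_index("species")
        assert row.loc["C", "loss_events"] == 1
        assert row.loc["A", "loss_events"] == 0

    def test_topology_mode_counts_shared_species_nodes(self):
        # ((A_1, A_2), B_1): one duplication node for species A
        inner = phylo.Node(length=0.1)
        inner.children = [phylo.Node("A_1", 0.1), phylo.Node("A_2", 0.1)]
        root = phylo.Node()
        root.children = [inner, phylo.Node("B_1", 0.1)]
        part = self._partition({"C1": {"A_1", "A_2", "B_1"}})
        sp = {"A_1": "A", "A_2": "A", "B_1": "B"}
        rep = infer_dup_loss(part, sp, ["A", "B"], clade_subtrees={"C1": root})
        row = rep.per_species.set_index("species")
        assert rep.mode == "topology"
        assert row.loc["A", "duplication_events"] == 1
        assert row.loc["A", "genes_involved"] == 2

    def test_genes_involved_at_least_events(self, burst_partition):
        part, _, species_of, _ = burst_partition
        species = sorted(set(species_of.values()))
        rep = infer_dup_loss(part, species_of, species)
        assert (rep.per_species.genes_involved >= rep.per_species.duplication_events).all()

    def test_recovery_against_simulated_truth(self, burst_dataset, burst_partition):
        genes, truth, _ = burst_dataset
        part, _, species_of, _ = burst_partition
        species = sorted(set(species_of.values()))
        rep = infer_dup_loss(part, species_of, species)
        obs = dict(zip(rep.per_species.species, rep.per_species.duplication_events))
        true_ev = truth.events_per_species("duplication")
        for sp in species:
            assert obs[sp] == true_ev.get(sp, 0)


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_value(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.225, abs=5e-4)
        assert df == pytest.approx(4.0)

    def test_zero_variance_equal_means(self):
        t, df, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_group(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestSelectionSummary:
    def test_all_purifying(self):
        pairs = [
            PairStats("a", "b", "x", "x", "C1", "paralog", omega=0.5)
            for _ in range(4)
        ]
        df = selection_summary(pairs)
        assert (
            df[df.group == "all"].pct_purifying.iloc[0] == pytest.approx(100.0)
        )

    def test_undefined_omega_excluded_from_denominator(self):
        pairs = [
            PairStats("a", "b", "x", "x", "C1", "paralog", omega=0.5),
            PairStats("c", "d", "x", "x", "C1", "paralog", omega=None),
            PairStats("e", "f", "x", "y", "C1", "ortholog", omega=1.5),
        ]
        df = selection_summary(pairs).set_index("group")
        assert df.loc["all", "n_pairs"] == 3
        assert df.loc["all", "n_defined"] == 2
        assert df.loc["all", "pct_purifying"] == pytest.approx(50.0)

    def test_simulated_purifying_fraction(self, burst_dataset, burst_partition):
        """An omega = 0.2 regime yields > 90% of pairs with Ka/Ks < 1."""
        genes, _, _ = burst_dataset
        part, _, species_of, aln = burst_partition
        rows = dict(zip(aln.gene_ids, aln.rows))
        pairs = compute_pair_stats(classify_pairs(part, species_of), rows)
        df = selection_summary(pairs).set_index("group")
        assert df.loc["all", "pct_purifying"] > 90.0
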