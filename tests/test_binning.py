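"""Binning procedures: taxonomy consensus (with exhaustive oracle), RPKG
coverage, contig clustering recovery, seeded read binning, cd-hit-style
redundancy semantics and read scaffolding."""

from collections import Counter
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from longbin.binning import (UNBINNED, UNCLASSIFIED, bin_contigs, bin_summary,
                             classify_contig, classify_contigs,
                             contig_coverage, remove_redundancy, scaffold_bin,
                             seeded_read_binning)
from longbin.records import SeqRecord, reverse_complement
from longbin.simdata import (CommunityMember, CommunitySpec, GenomeSpec,
                             ReadSimSpec, fragment_genome, generate_genome,
                             make_marker_reference, simulate_gene_table,
                             simulate_reads)


class TestClassifyContig:
    @pytest.mark.parametrize("labels,expected", [
        (["A"] * 6 + ["B"] * 4, "A"),
        (["A"] * 5 + ["B"] * 5, UNCLASSIFIED),        # two-way tie at 50%
        (["A"] * 5 + [None] * 5, "A"),                # unlabeled in denominator
        (["A"] * 4 + [None] * 6, UNCLASSIFIED),       # 40% < 50%
        ([], UNCLASSIFIED),
    ])
    def test_rules(self, labels, expected):
        assert classify_contig(10000, labels) == expected

    def test_short_contig_unclassified(self):
        assert classify_contig(4000, ["A"] * 10) == UNCLASSIFIED

    def test_exhaustive_oracle(self):
        """Agreement with brute-force counting over all multisets of up to
        12 labels drawn from {A, B, unlabeled}."""
        def oracle(labels):
            if not labels:
                return UNCLASSIFIED
            n = len(labels)
            counts = Counter(l for l in labels if l)
            winners = [lab for lab, c in counts.items() if c / n >= 0.5]
            if len(winners) != 1:
                return UNCLASSIFIED
            w = winners[0]
            # a second label matching the winner's count is a tie
            if any(c == counts[w] for lab, c in counts.items() if lab != w):
                return UNCLASSIFIED
            return w

        checked = 0
        for size in range(0, 13):
            for combo in combinations_with_replacement(["A", "B", None], size):
                labels = list(combo)
                assert classify_contig(10000, labels) == oracle(labels), labels
                checked += 1
        assert checked > 400


class TestContigCoverage:
    def test_rpkg_normalization(self, genome_50k):
        contigs = [SeqRecord("c1", genome_50k.seq[:10000]),
                   SeqRecord("c2", genome_50k.seq[:20000])]
        reads = [SeqRecord(f"r{i}", genome_50k.seq[i * 37: i * 37 + 150])
                 for i in range(60)]
        cov = contig_coverage(contigs, {"M": reads}, subsample=None)
        # reads come from the shared 10 kb prefix; best-hit tie-breaking is
        # deterministic, and RPKG normalizes per contig kilobase
        assert (cov.loc["c1", "M"] > 0) or (cov.loc["c2", "M"] > 0)

    def test_no_mapped_reads_zero(self, genome_50k, genome_50k_other):
        contigs = [SeqRecord("c", genome_50k.seq[:10000])]
        reads = [SeqRecord("r", genome_50k_other.seq[:500])]
        cov = contig_coverage(contigs, {"M": reads}, subsample=None)
        assert cov.loc["c", "M"] == 0.0

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError):
            contig_coverage([SeqRecord("c", "")], {"M": []})

    def test_no_metagenome_rejected(self, genome_50k):
        with pytest.raises(ValueError):
            contig_coverage([SeqRecord("c", genome_50k.seq[:1000])], {})


@pytest.fixture(scope="module")
def five_genome_benchmark():
    gcs = [0.35, 0.425, 0.50, 0.575, 0.65]
    specs = [GenomeSpec(f"G{i}", 120000, gcs[i], signature_seed=100 + i)
             for i in range(5)]
    genomes = [generate_genome(s, rng_seed=1) for s in specs]
    contigs = []
    for i, g in enumerate(genomes):
        contigs += fragment_genome(g, 5000, 40000, rng_seed=10 + i)
    abunds = [[0.4, 0.3, 0.15, 0.1, 0.05],
              [0.05, 0.1, 0.15, 0.3, 0.4],
              [0.2, 0.05, 0.4, 0.05, 0.3]]
    metagenomes = {}
    for m, ab in enumerate(abunds):
        spec = CommunitySpec([CommunityMember(specs[i], ab[i]) for i in range(5)],
                             rng_seed=1)
        reads, _ = simulate_reads(spec, ReadSimSpec.short(n_reads=9000,
                                                          rng_seed=50 + m))
        metagenomes[f"M{m}"] = reads
    phyla = {"G0": "PhylA", "G1": "PhylA", "G2": "PhylB",
             "G3": "PhylB", "G4": "PhylC"}
    genes = pd.concat([simulate_gene_table(c, phyla[c.meta["genome"]],
                                           wrong_labels=tuple(set(phyla.values())),
                                           rng_seed=i)
                       for i, c in enumerate(contigs)], ignore_index=True)
    return genomes, contigs, metagenomes, genes


class TestBinContigs:
    def test_five_genome_recovery(self, five_genome_benchmark):
        genomes, contigs, metagenomes, genes = five_genome_benchmark
        cov = contig_coverage(contigs, metagenomes, subsample=None)
        tax = classify_contigs(contigs, genes)
        ba = bin_contigs(contigs, cov, tax)
        truth = [c.meta["genome"] for c in contigs]
        pred = [ba.assignments[c.id] for c in contigs]
        assert adjusted_rand_score(truth, pred) >= 0.90

    def test_single_genome_single_bin(self, genome_50k):
        contigs = fragment_genome(genome_50k, 5000, 15000, rng_seed=2)
        reads = [SeqRecord(f"r{i}", genome_50k.seq[i * 101: i * 101 + 150])
                 for i in range(200)]
        cov = contig_coverage(contigs, {"M": reads}, subsample=None)
        tax = {c.id: "PhylX" for c in contigs}
        ba = bin_contigs(contigs, cov, tax)
        labels = {ba.assignments[c.id] for c in contigs}
        assert len(labels - {UNBINNED}) == 1
        truth = ["g"] * len(contigs)
        pred = [ba.assignments[c.id] for c in contigs]
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)

    def test_mismatched_features_rejected(self, genome_50k):
        contigs = fragment_genome(genome_50k, 5000, 15000, rng_seed=2)
        cov = pd.DataFrame({"M": [1.0]}, index=["other"])
        with pytest.raises(ValueError):
            bin_contigs(contigs, cov, {c.id: "X" for c in contigs})


@pytest.fixture(scope="module")
def three_populations():
    refs = make_marker_reference(["T;A", "T;B", "T;C"], rng_seed=7)
    specs = [GenomeSpec(f"P{i}", 100000, 0.40 + 0.07 * i,
                        signature_seed=200 + i,
                        marker_template=refs[i].seq, marker_divergence=0.05)
             for i in range(3)]
    cspec = CommunitySpec(
        [CommunityMember(specs[i], [0.5, 0.3, 0.2][i], 0.02, 4)
         for i in range(3)], rng_seed=3)
    reads, truth = simulate_reads(
        cspec, ReadSimSpec(mean_length=4000, length_sd=800, n_reads=600,
                           error_rate=0.003, rng_seed=11))
    tmap = dict(zip(truth.read_id, truth.genome))
    # one long seed read per population (stands in for marker carriers)
    seeds = [next(r.id for r in reads
                  if tmap[r.id] == f"P{gi}" and len(r.seq) > 3000)
             for gi in range(3)]
    return reads, truth, tmap, seeds


class TestSeededReadBinning:
    def test_purity_above_080(self, three_populations):
        reads, truth, tmap, seeds = three_populations
        ba = seeded_read_binning(reads, seeds)
        assert len(ba.labels) == 3
        for lab in ba.labels:
            members = ba.members_of(lab)
            counts = Counter(tmap[m] for m in members)
            purity = counts.most_common(1)[0][1] / len(members)
            assert purity >= 0.80

    def test_known_genome_reads_removed(self, three_populations, genome_50k):
        reads, truth, tmap, seeds = three_populations
        known_read = SeqRecord("planted", genome_50k.seq[10000:14000])
        ba = seeded_read_binning(reads + [known_read], seeds,
                                 known_genomes=[genome_50k])
        assert ba.assignments["planted"] == UNBINNED

    def test_same_population_seeds_merge(self, three_populations):
        reads, truth, tmap, seeds = three_populations
        # longest same-population reads: composition estimates are tight, so
        # their feature distance to the existing seed sits below the gate
        extra = [r.id for r in sorted(reads, key=len, reverse=True)
                 if tmap[r.id] == tmap[seeds[0]] and r.id != seeds[0]][:2]
        ba = seeded_read_binning(reads, seeds + extra)
        assert len(ba.labels) == 3

    def test_no_seeds_rejected(self, three_populations):
        reads, *_ = three_populations
        with pytest.raises(ValueError):
            seeded_read_binning(reads, [])


class TestRemoveRedundancy:
    def test_exact_duplicates_collapse(self, genome_50k):
        reads = [SeqRecord(f"d{i}", genome_50k.seq[:3000]) for i in range(10)]
        kept, members = remove_redundancy(reads)
        assert len(kept) == 1
        assert len(members[kept[0].id]) == 10

    def test_95pct_pairs_survive(self, genome_50k, rng):
        from longbin.simdata import mutate_sites
        a = SeqRecord("a", genome_50k.seq[:3000])
        b = SeqRecord("b", mutate_sites(a.seq, 0.05, rng))
        kept, _ = remove_redundancy([a, b])
        assert len(kept) == 2

    def test_nested_substring_removed(self, genome_50k):
        long_read = SeqRecord("long", genome_50k.seq[:6000])
        nested = SeqRecord("nested", genome_50k.seq[1500:4500])  # 50% of longer
        kept, members = remove_redundancy([long_read, nested])
        assert [k.id for k in kept] == ["long"]
        assert members["long"] == ["long", "nested"]

    def test_idempotent(self, genome_50k, rng):
        from longbin.simdata import mutate_sites
        reads = [SeqRecord(f"r{i}",
                           mutate_sites(genome_50k.seq[j * 2000:(j + 2) * 2000],
                                        0.003 * i, rng))
                 for i, j in enumerate([0, 0, 3, 5, 5])]
        kept1, _ = remove_redundancy(reads)
        kept2, _ = remove_redundancy(kept1)
        assert [k.id for k in kept1] == [k.id for k in kept2]


class TestScaffoldBin:
    def test_three_read_tiling_merges(self, genome_50k):
        reads = [SeqRecord("r1", genome_50k.seq[0:8000]),
                 SeqRecord("r2", genome_50k.seq[6000:14000]),
                 SeqRecord("r3", genome_50k.seq[12000:20000])]
        merged = scaffold_bin(reads)
        assert len(merged) == 1
        assert len(merged[0].seq) == 20000
        assert merged[0].seq == genome_50k.seq[:20000]

    def test_mixed_orientation_tiling(self, genome_50k):
        reads = [SeqRecord("r1", genome_50k.seq[0:8000]),
                 SeqRecord("r2", reverse_complement(genome_50k.seq[6000:14000]))]
        merged = scaffold_bin(reads)
        assert len(merged) == 1
        assert len(merged[0].seq) == 14000

    def test_no_overlap_unchanged(self, genome_50k, genome_50k_other):
        reads = [SeqRecord("a", genome_50k.seq[:5000]),
                 SeqRecord("b", genome_50k_other.seq[:5000])]
        merged = scaffold_bin(reads)
        assert sorted(m.id for m in merged) == ["a", "b"]

    def test_fork_not_merged(self, genome_50k, genome_50k_other):
        stem = genome_50k.seq[0:6000]
        fork1 = genome_50k.seq[4000:12000]
        fork2 = genome_50k.seq[4000:6000] + genome_50k_other.seq[:6000]
        reads = [SeqRecord("stem", stem), SeqRecord("f1", fork1),
                 SeqRecord("f2", fork2)]
        merged = scaffold_bin(reads)
        # the stem overlaps two incompatible extensions: no merge across it
        assert len(merged) == 3


class TestBinSummary:
    def test_two_member_gc_sd(self):
        a = SeqRecord("a", "AT" * 1500 + "GC" * 1000)   # 5 kb, GC 40%
        b = SeqRecord("b", "AT" * 1250 + "GC" * 1250)   # 5 kb, GC 50%
        row = bin_summary([a, b])
        assert row["total_size_bp"] == 10000
        assert row["gc_mean_pct"] == pytest.approx(45.0)
        assert row["gc_sd_pct"] == pytest.approx(7.0710678, abs=1e-4)

    def test_gene_stats(self):
        genes = pd.DataFrame(dict(contig_id=["a", "a"], gene_id=["g1", "g2"],
                                  start=[0, 1000], end=[500, 1600],
                                  strand=["+", "+"],
                                  best_hit_taxon=["X", "X"]))
        row = bin_summary([SeqRecord("a", "ACGT" * 1000)], genes)
        assert row["n_genes"] == 2
        assert row["mean_gene_size_bp"] == pytest.approx(550.0)

    def test_zero_genes_missing_mean(self):
        genes = pd.DataFrame(columns=["contig_id", "gene_id", "start", "end",
                                      "strand", "best_hit_taxon"])
        row = bin_summary([SeqRecord("a", "ACGT" * 100)], genes)
        assert row["n_genes"] == 0
        assert np.isnan(row["mean_gene_size_bp"])

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_summary([])
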