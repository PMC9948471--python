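"""Recruitment statistics: RPKG closed forms, presence truth table, breadth
and masking, ANIr recovery across divergence levels, fragment ANI, genome
dereplication and AAI networks."""

import numpy as np
import pytest

from longbin.records import SeqRecord
from longbin.recruitment import (ani, ani_symmetric, anir, aai_network,
                                 dereplicate_genomes, is_present,
                                 proteome_pair, recruit, recruit_sweep,
                                 recruitment_matrix, rpkg)
from longbin.simdata import (CommunityMember, CommunitySpec, GenomeSpec,
                             ReadSimSpec, build_community, diversify_population,
                             generate_genome, mutate_sites, simulate_reads)

from conftest import random_dna


class TestRpkgFormula:
    def test_worked_case(self):
        assert rpkg(100, 10_000, 1e9) == pytest.approx(10.0)

    def test_halves_when_genome_doubles(self):
        assert rpkg(100, 20_000, 1e9) == pytest.approx(5.0)

    def test_zero_reads(self):
        assert rpkg(0, 10_000, 1e9) == 0.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            rpkg(1, 0, 1e9)
        with pytest.raises(ValueError):
            rpkg(1, 1000, 0)


class TestPresenceRule:
    @pytest.mark.parametrize("r,b,expected", [
        (2.9, 0.69, False), (2.9, 0.70, False),
        (3.0, 0.69, False), (3.0, 0.70, True),
    ])
    def test_truth_table(self, r, b, expected):
        assert is_present(r, b) is expected


class TestRecruit:
    def test_simulated_depth(self, genome_50k):
        spec = CommunitySpec([CommunityMember(
            GenomeSpec("g50", 50000, 0.5, 11), 1.0)], rng_seed=1)
        reads, _ = simulate_reads(spec, ReadSimSpec(
            mean_length=2000, length_sd=300, n_reads=500, error_rate=0.005,
            rng_seed=4))
        p = recruit(genome_50k, reads, metagenome_bp=1e9)
        assert p.n_reads == 500
        assert p.rpkg == pytest.approx(rpkg(500, 50000, 1e9))
        assert p.breadth > 0.95
        assert p.present

    def test_absent_genome(self, genome_50k, genome_50k_other):
        reads = [SeqRecord(f"r{i}", genome_50k_other.seq[i * 400:(i * 400) + 300])
                 for i in range(30)]
        p = recruit(genome_50k, reads, metagenome_bp=1e9)
        assert p.n_reads == 0
        assert not p.present

    def test_half_genome_pileup_not_present(self, genome_50k):
        # plenty of reads but only on one half: high RPKG, low breadth
        reads = [SeqRecord(f"r{i}", genome_50k.seq[(i * 97) % 20000:
                                                   (i * 97) % 20000 + 300])
                 for i in range(400)]
        p = recruit(genome_50k, reads, metagenome_bp=1e7)
        assert p.rpkg > 3
        assert p.breadth < 0.7
        assert not p.present

    def test_mask_excluded_from_length_and_mapping(self, genome_50k):
        reads = [SeqRecord(f"r{i}", genome_50k.seq[i * 250: i * 250 + 200])
                 for i in range(100)]
        full = recruit(genome_50k, reads, metagenome_bp=1e9)
        masked = recruit(genome_50k, reads, metagenome_bp=1e9,
                         rrna_mask=[(0, 25000)])
        assert masked.n_reads < full.n_reads
        # reads over the unmasked half still count against a 25 kb genome
        assert masked.rpkg == pytest.approx(
            rpkg(masked.n_reads, 25000, 1e9))

    def test_fully_masked_rejected(self, genome_50k):
        with pytest.raises(ValueError):
            recruit(genome_50k, [], rrna_mask=[(0, len(genome_50k))],
                    metagenome_bp=1e9)


class TestAnir:
    def test_error_free_reads_100(self, genome_50k):
        reads = [SeqRecord(f"r{i}", genome_50k.seq[i * 500: i * 500 + 400])
                 for i in range(50)]
        assert anir(genome_50k, reads) == pytest.approx(100.0)

    @pytest.mark.parametrize("d", [0.0, 0.01, 0.02, 0.04])
    def test_divergence_recovery(self, d):
        spec = CommunitySpec([CommunityMember(
            GenomeSpec("g", 60000, 0.5, 31), 1.0, population_divergence=d,
            n_strains=3)], rng_seed=2)
        community = build_community(spec)
        reads, _ = simulate_reads(community, ReadSimSpec(
            mean_length=2000, length_sd=300, n_reads=250, error_rate=0.0,
            rng_seed=6))
        got = anir(community.genomes[0], reads)
        assert got == pytest.approx(100 * (1 - d), abs=0.3)

    def test_no_passing_reads_nan(self, genome_50k):
        reads = [SeqRecord("r", random_dna(500, 77))]
        assert np.isnan(anir(genome_50k, reads))


class TestAni:
    def test_self_is_100(self, genome_50k):
        val, frac = ani(genome_50k, genome_50k)
        assert val == 100.0
        assert frac == 1.0

    def test_five_percent_mutant(self, genome_50k, rng):
        other = SeqRecord("m", mutate_sites(genome_50k.seq, 0.05, rng))
        val, frac = ani_symmetric(genome_50k, other)
        assert val == pytest.approx(95.0, abs=0.3)
        assert frac > 0.9

    def test_unrelated_missing(self, genome_50k, genome_50k_other):
        val, frac = ani(genome_50k, genome_50k_other)
        assert np.isnan(val)
        assert frac == 0.0

    def test_symmetry(self, genome_50k, rng):
        other = SeqRecord("m", mutate_sites(genome_50k.seq, 0.03, rng))
        ab = ani_symmetric(genome_50k, other)[0]
        ba = ani_symmetric(other, genome_50k)[0]
        assert ab == pytest.approx(ba, abs=0.3)


class TestDereplicateGenomes:
    def test_population_collapses(self, genome_50k):
        strains = diversify_population(genome_50k, 3, 0.01, rng_seed=3)
        reps, clusters = dereplicate_genomes([genome_50k] + strains)
        assert len(reps) == 1
        assert len(clusters[reps[0].id]) == 4

    def test_divergent_genomes_stay(self, genome_50k, rng):
        other = SeqRecord("m", mutate_sites(genome_50k.seq, 0.10, rng))
        reps, _ = dereplicate_genomes([genome_50k, other])
        assert len(reps) == 2

    def test_single_genome(self, genome_50k):
        reps, clusters = dereplicate_genomes([genome_50k])
        assert [r.id for r in reps] == [genome_50k.id]


def _random_peptides(n, length, seed):
    r = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return [SeqRecord(f"p{seed}_{i}",
                      "".join(aas[j] for j in r.integers(0, 20, size=length)))
            for i in range(n)]


class TestAaiNetwork:
    def test_identical_proteomes(self):
        prots = _random_peptides(12, 120, 1)
        pair = proteome_pair("a", prots, "b",
                             [SeqRecord(p.id + "x", p.seq) for p in prots])
        assert pair.aai == pytest.approx(100.0)
        assert pair.of == pytest.approx(1.0)

    def test_half_shared(self):
        shared = _random_peptides(6, 120, 2)
        a = shared + _random_peptides(6, 120, 3)
        b = [SeqRecord(p.id + "b", p.seq) for p in shared] + _random_peptides(6, 120, 4)
        pair = proteome_pair("a", a, "b", b)
        assert pair.of == pytest.approx(0.5, abs=0.1)
        assert pair.aai == pytest.approx(100.0, abs=1.0)

    def test_unrelated_no_edge(self):
        edges = aai_network({"a": _random_peptides(8, 120, 5),
                             "b": _random_peptides(8, 120, 6)})
        assert edges == []

    def test_empty_proteome_warns_and_excluded(self):
        with pytest.warns(UserWarning):
            edges = aai_network({"a": _random_peptides(4, 100, 7), "b": []})
        assert edges == []


class TestRecruitSweepAndMatrix:
    def test_multi_metagenome_presence_flags(self, genome_50k, genome_50k_other):
        dense = [SeqRecord(f"d{i}", genome_50k.seq[i * 120: i * 120 + 300])
                 for i in range(400)]
        sparse = [SeqRecord(f"s{i}", genome_50k_other.seq[i * 120: i * 120 + 300])
                  for i in range(400)]
        mat = recruitment_matrix([genome_50k], {"has": dense, "lacks": sparse},
                                 identity_levels=(95.0,))
        by_mg = mat.set_index("metagenome")
        assert bool(by_mg.loc["has", "present"])
        assert not bool(by_mg.loc["lacks", "present"])

    def test_lower_identity_never_fewer_reads(self, two_genome_reads):
        community, reads, _ = two_genome_reads
        g = community.genomes[0]
        mat = recruitment_matrix([g], {"M": reads[:300]},
                                 identity_levels=(95.0, 70.0))
        n95 = int(mat[mat.identity_level == 95.0].n_reads.iloc[0])
        n70 = int(mat[mat.identity_level == 70.0].n_reads.iloc[0])
        assert n70 >= n95

    def test_sweep_best_hit_across_genomes(self, two_genome_reads):
        community, reads, truth = two_genome_reads
        profiles = recruit_sweep(community.genomes, reads, metagenome_bp=1e9)
        counts = truth.genome.value_counts()
        got = {p.genome_id: p.n_reads for p in profiles}
        assert sum(got.values()) <= len(reads)
        for g in ("A", "B"):
            assert got[g] == pytest.approx(counts[g], rel=0.05)
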