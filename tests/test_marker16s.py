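"""Marker detection E-values, validation coverage, classification gates,
greedy dereplication (with brute-force oracle) and community profiles."""

import numpy as np
import pytest

from longbin.marker16s import (UNCLASSIFIED, classify_marker,
                               dereplicate_markers, evalue,
                               find_marker_candidates, karlin_lambda,
                               read_marker_fasta, taxon_profile,
                               validate_marker, write_marker_fasta)
from longbin.mapping import align_pair
from longbin.records import SeqRecord, reverse_complement
from longbin.simdata import (GenomeSpec, diversify_population,
                             generate_genome, make_marker_reference,
                             mutate_sites)

from conftest import random_dna


@pytest.fixture(scope="module")
def marker_refs():
    return make_marker_reference(
        ["Bacteria;PhylA;ClassA1", "Bacteria;PhylB;ClassB1"], rng_seed=3)


@pytest.fixture(scope="module")
def read_with_marker(marker_refs):
    g = generate_genome(GenomeSpec("g", 30000, 0.5, 21,
                                   marker_template=marker_refs[0].seq,
                                   marker_divergence=0.03), rng_seed=2)
    s, e = g.meta["marker_start"], g.meta["marker_end"]
    return SeqRecord("read", g.seq[max(0, s - 700): e + 700]), g


class TestCandidates:
    def test_exact_marker_has_tiny_evalue(self, marker_refs):
        read = SeqRecord("r", random_dna(500, 1) + marker_refs[0].seq
                         + random_dna(500, 2))
        (hit,) = find_marker_candidates([read], marker_refs)
        assert hit.evalue < 1e-100
        assert hit.best_ref == marker_refs[0].id
        assert hit.segment.seq == marker_refs[0].seq

    def test_karlin_altschul_closed_form(self):
        lam = karlin_lambda()
        # lambda solves (1/4)e^lam + (3/4)e^(-2 lam) = 1
        assert 0.25 * np.exp(lam) + 0.75 * np.exp(-2 * lam) == pytest.approx(1.0)
        # a 1500-base exact match scores 1500: E astronomically small
        assert evalue(1500, 1500, 3000) < 1e-300

    def test_random_short_read_no_candidate(self, marker_refs):
        reads = [SeqRecord(f"r{i}", random_dna(150, 500 + i)) for i in range(20)]
        assert find_marker_candidates(reads, marker_refs) == []

    def test_minus_strand_segment_reoriented(self, marker_refs):
        read = SeqRecord("r", random_dna(400, 3)
                         + reverse_complement(marker_refs[0].seq)
                         + random_dna(400, 4))
        (hit,) = find_marker_candidates([read], marker_refs)
        assert hit.strand == "-"
        assert hit.segment.seq == marker_refs[0].seq

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            find_marker_candidates([SeqRecord("r", "ACGT" * 100)], [])


class TestValidateClassify:
    def test_full_length_valid(self, read_with_marker, marker_refs):
        read, _ = read_with_marker
        (hit,) = find_marker_candidates([read], marker_refs)
        assert validate_marker(hit, marker_refs)

    def test_short_fragment_invalid(self, marker_refs):
        read = SeqRecord("r", random_dna(300, 9) + marker_refs[0].seq[:120]
                         + random_dna(300, 10))
        hits = find_marker_candidates([read], marker_refs)
        assert all(not validate_marker(h, marker_refs) for h in hits)

    def test_zero_threshold_always_valid(self, marker_refs):
        read = SeqRecord("r", random_dna(300, 9) + marker_refs[0].seq[:200]
                         + random_dna(300, 10))
        for h in find_marker_candidates([read], marker_refs):
            assert validate_marker(h, marker_refs, min_model_fraction=0.0)

    def test_long_class_classification(self, read_with_marker, marker_refs):
        read, _ = read_with_marker
        (hit,) = find_marker_candidates([read], marker_refs)
        path = classify_marker(hit, marker_refs, "long")
        assert path == ("Bacteria", "PhylA", "ClassA1")

    def test_long_class_needs_1000_bases(self, marker_refs):
        read = SeqRecord("r", random_dna(200, 11) + marker_refs[0].seq[:800]
                         + random_dna(200, 12))
        (hit,) = find_marker_candidates([read], marker_refs)
        assert classify_marker(hit, marker_refs, "long") == UNCLASSIFIED

    def test_short_class_gates(self, marker_refs):
        # 120 aligned bases at high identity: classified
        read = SeqRecord("r", marker_refs[0].seq[200:320])
        (hit,) = find_marker_candidates([read], marker_refs, max_evalue=1e-2)
        assert classify_marker(hit, marker_refs, "short") != UNCLASSIFIED
        # 60 aligned bases: fails the 90-base gate
        read2 = SeqRecord("r2", marker_refs[0].seq[200:260])
        hits = find_marker_candidates([read2], marker_refs, max_evalue=1e-2)
        for h in hits:
            assert classify_marker(h, marker_refs, "short") == UNCLASSIFIED

    def test_unknown_class_rejected(self, read_with_marker, marker_refs):
        read, _ = read_with_marker
        (hit,) = find_marker_candidates([read], marker_refs)
        with pytest.raises(ValueError):
            classify_marker(hit, marker_refs, "medium")


class TestDereplicate:
    def test_population_collapses_to_one(self, marker_refs):
        parent = SeqRecord("m", marker_refs[0].seq)
        segs = diversify_population(parent, 5, 0.01, rng_seed=4)
        reps, members = dereplicate_markers(segs)
        assert len(reps) == 1
        assert sorted(sum(members.values(), [])) == sorted(s.id for s in segs)

    def test_divergent_markers_stay_apart(self, marker_refs):
        rng = np.random.default_rng(5)
        a = SeqRecord("a", marker_refs[0].seq)
        b = SeqRecord("b", mutate_sites(marker_refs[0].seq, 0.10, rng))
        reps, _ = dereplicate_markers([a, b])
        assert len(reps) == 2

    def test_empty_input(self):
        reps, members = dereplicate_markers([])
        assert reps == [] and members == {}

    def test_brute_force_oracle(self, marker_refs):
        """Every member is >=97% identical to its representative over >=90%
        of its own length, and no two representatives collapse."""
        rng = np.random.default_rng(6)
        segs = []
        for fam in range(3):
            parent = mutate_sites(marker_refs[0].seq, 0.08 * fam, rng)
            for i in range(4):
                segs.append(SeqRecord(f"f{fam}s{i}", mutate_sites(parent, 0.005, rng)))
        reps, members = dereplicate_markers(segs)
        by_id = {s.id: s for s in segs}

        def matches(seg, rep):
            for aln in align_pair(seg, rep, 97.0, 50):
                qs, qe = aln.query_interval
                if qe - qs >= 0.9 * len(seg):
                    return True
            return False

        for rep_id, mem in members.items():
            for m in mem:
                if m != rep_id:
                    assert matches(by_id[m], by_id[rep_id])
        for i, r1 in enumerate(reps):
            for r2 in reps[:i]:
                assert not matches(r1, r2)


class TestTaxonProfile:
    def test_direct_tally(self):
        hits = [("Bacteria", "A")] * 60 + [("Bacteria", "B")] * 40
        prof = taxon_profile(hits, level=1)
        assert prof.fractions == {"A": 0.6, "B": 0.4}
        assert prof.n_total == 100

    def test_display_floor_strict(self):
        hits = [("Bacteria", "A")] * 99 + [("Bacteria", "B")]
        prof = taxon_profile(hits, level=1, min_display_fraction=0.01)
        assert "B" not in prof.display           # 1% is not 'larger than 1%'
        assert prof.display.get("other") == pytest.approx(0.01)
        assert prof.fractions["B"] == pytest.approx(0.01)  # retained in data

    def test_empty(self):
        prof = taxon_profile([], level=1)
        assert prof.n_total == 0 and prof.fractions == {}

    def test_unclassified_excluded(self):
        prof = taxon_profile([UNCLASSIFIED, ("Bacteria", "A")], level=1)
        assert prof.n_total == 1


def test_marker_fasta_roundtrip(tmp_path, marker_refs):
    path = tmp_path / "refs.fasta"
    write_marker_fasta(marker_refs, path)
    back = read_marker_fasta(path)
    assert [(r.id, r.seq, r.meta["taxonomy"]) for r in back] == \
           [(r.id, r.seq, r.meta["taxonomy"]) for r in marker_refs]
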