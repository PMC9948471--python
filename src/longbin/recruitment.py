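"""Fragment recruitment, presence calling, ANIr, fragment ANI, genome
dereplication and AAI / shared-protein networks.

Recruitment maps metagenomic reads to a genome at an identity/length gate
(default 95% over >= 50 columns, best hit per read) and summarizes:

* RPKG  — recruited reads per genome-kb per metagenome-Gb;
* breadth — fraction of (unmasked) genome positions covered by >= 1 read;
* presence — RPKG >= 3 AND breadth >= 0.7 ("less than three RPKG" and
  "less than 70% covered" both mean absent);
* ANIr — unweighted mean identity of best-hit reads at a permissive gate
  (80% / 50 bp), the intra-population microdiversity statistic.

rRNA-like regions can be masked (BED-style 0-based half-open intervals):
masked bases are excluded both from mapping and from the genome length used
for RPKG and breadth.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .mapping import ReferenceIndex, align_pair, map_reads
from .records import SeqRecord

MIN_RPKG_PRESENT = 3.0
MIN_BREADTH_PRESENT = 0.7


@dataclass
class RecruitmentProfile:
    genome_id: str
    metagenome_id: str
    n_reads: int
    rpkg: float
    breadth: float
    anir: float              # NaN when no reads pass the ANIr gate
    present: bool
    identity_level: float = 95.0


@dataclass
class ProteomePair:
    genome_a: str
    genome_b: str
    n_rbh: int
    aai: float               # mean percent identity over RBH pairs
    of: float                # orthologous fraction = n_rbh / min proteome size


# ---------------------------------------------------------------------------
# RPKG / presence primitives
# ---------------------------------------------------------------------------

def rpkg(n_reads: int, genome_bp: int, metagenome_bp: float) -> float:
    """Reads per genome-kilobase per metagenome-gigabase."""
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")
    if metagenome_bp <= 0:
        raise ValueError("metagenome size must be positive")
    return n_reads / ((genome_bp / 1e3) * (metagenome_bp / 1e9))


def is_present(rpkg_value: float, breadth: float,
               min_rpkg: float = MIN_RPKG_PRESENT,
               min_breadth: float = MIN_BREADTH_PRESENT) -> bool:
    return rpkg_value >= min_rpkg and breadth >= min_breadth


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
    return total


def _mask_sequence(seq: str, mask: list[tuple[int, int]]) -> tuple[str, int]:
    """N-out masked intervals; returns (masked sequence, unmasked length)."""
    arr = list(seq)
    masked = 0
    for s, e in mask:
        s, e = max(0, s), min(len(seq), e)
        for i in range(s, e):
            if arr[i] != "N":
                arr[i] = "N"
                masked += 1
    return "".join(arr), len(seq) - masked


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def recruit(genome: SeqRecord, metagenome_reads: list[SeqRecord],
            metagenome_id: str = "metagenome",
            min_identity: float = 95.0, min_aln: int = 50,
            rrna_mask: list[tuple[int, int]] | None = None,
            metagenome_bp: float | None = None,
            anir_gate: tuple[float, int] = (80.0, 50),
            circular: bool | None = None) -> RecruitmentProfile:
    """Best-hit recruitment of a read set against one genome."""
    if len(genome) == 0:
        raise ValueError("empty genome")
    seq = genome.seq
    unmasked = len(seq)
    if rrna_mask:
        seq, unmasked = _mask_sequence(seq, rrna_mask)
        if unmasked == 0:
            raise ValueError("genome fully masked")
    circular = genome.circular if circular is None else circular
    L = len(seq)
    ref_seq = seq
    if circular and metagenome_reads:
        ext = min(L, max(len(r) for r in metagenome_reads))
        ref_seq = seq + seq[:ext]
    ref = SeqRecord(genome.id, ref_seq)

    if metagenome_bp is None:
        metagenome_bp = float(sum(len(r) for r in metagenome_reads))

    gate_id, gate_len = anir_gate
    loose = map_reads(metagenome_reads, [ref], gate_id, gate_len,
                      mode="best_hit", seed_k=11)
    strict = [a for a in loose
              if a.pct_identity >= min_identity and a.aln_len >= min_aln]

    intervals = []
    for a in strict:
        s, e = a.subject_interval
        if s < L:
            intervals.append((s, min(e, L)))
        if e > L:  # wrapped onto the circular extension
            intervals.append((0, e - L))
        if s >= L:
            intervals.append((s - L, e - L))
    breadth = _union_length(intervals) / unmasked if unmasked else 0.0
    n = len(strict)
    r = rpkg(n, unmasked, metagenome_bp) if metagenome_bp > 0 else 0.0
    anir_val = float(np.mean([a.pct_identity for a in loose])) if loose else float("nan")
    return RecruitmentProfile(genome.id, metagenome_id, n, r, min(breadth, 1.0),
                              anir_val, is_present(r, breadth), min_identity)


def anir(genome: SeqRecord, metagenome_reads: list[SeqRecord],
         gate_identity: float = 80.0, gate_aln: int = 50) -> float:
    """Unweighted mean best-hit read identity at the ANIr gate; NaN when no
    reads pass."""
    alns = map_reads(metagenome_reads, [genome], gate_identity, gate_aln,
                     mode="best_hit", seed_k=11)
    if not alns:
        return float("nan")
    return float(np.mean([a.pct_identity for a in alns]))


def recruit_sweep(genomes: list[SeqRecord], metagenome_reads: list[SeqRecord],
                  metagenome_id: str = "metagenome",
                  min_identity: float = 95.0, min_aln: int = 50,
                  metagenome_bp: float | None = None) -> list[RecruitmentProfile]:
    """Recruit one read set against a genome SET with a single best hit per
    read across all genomes (a read recruited by two genomes counts only for
    its best match).  Returns one profile per genome."""
    if metagenome_bp is None:
        metagenome_bp = float(sum(len(r) for r in metagenome_reads))
    index = ReferenceIndex(genomes, k=15 if min_identity >= 90 else 11)
    per_genome: dict[str, list] = {g.id: [] for g in genomes}
    for a in map_reads(metagenome_reads, index, min_identity, min_aln,
                       mode="best_hit"):
        per_genome[a.subject_id].append(a)
    out = []
    for g in genomes:
        alns = per_genome[g.id]
        intervals = [a.subject_interval for a in alns]
        breadth = _union_length(intervals) / len(g)
        n = len(alns)
        r = rpkg(n, len(g), metagenome_bp)
        anir_val = float(np.mean([a.pct_identity for a in alns])) if alns \
            else float("nan")
        out.append(RecruitmentProfile(g.id, metagenome_id, n, r,
                                      min(breadth, 1.0), anir_val,
                                      is_present(r, breadth), min_identity))
    return out


def recruitment_matrix(genomes: list[SeqRecord],
                       metagenomes: dict[str, list[SeqRecord]],
                       identity_levels: tuple[float, ...] = (95.0, 70.0),
                       min_aln: int = 50,
                       rrna_masks: dict[str, list[tuple[int, int]]] | None = None
                       ) -> pd.DataFrame:
    """Long-format table of RecruitmentProfiles per (genome, metagenome,
    identity level).  Lowering the identity level never decreases n_reads."""
    rows = []
    for name, reads in metagenomes.items():
        mg_bp = float(sum(len(r) for r in reads))
        for g in genomes:
            for level in identity_levels:
                p = recruit(g, reads, name, min_identity=level, min_aln=min_aln,
                            metagenome_bp=mg_bp,
                            rrna_mask=(rrna_masks or {}).get(g.id),
                            anir_gate=(min(70.0, level), min_aln))
                rows.append(dict(genome=p.genome_id, metagenome=name,
                                 identity_level=level, n_reads=p.n_reads,
                                 rpkg=p.rpkg, breadth=p.breadth, anir=p.anir,
                                 present=p.present))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fragment-based ANI and genome dereplication
# ---------------------------------------------------------------------------

def ani(genome_a: SeqRecord, genome_b: SeqRecord, fragment: int = 1020,
        min_frag_identity: float = 30.0, min_frag_coverage: float = 0.7
        ) -> tuple[float, float]:
    """One-way fragment ANI: cut genome_a into consecutive fragments, best-hit
    align each to genome_b, keep fragments aligning at >= 30% identity over
    >= 70% of their length; returns (mean identity of kept fragments,
    kept fraction).  (NaN, 0.0) when nothing aligns."""
    if len(genome_a) < fragment:
        raise ValueError("genome_a shorter than one fragment")
    frags = [SeqRecord(f"f{i}", genome_a.seq[s:s + fragment])
             for i, s in enumerate(range(0, len(genome_a) - fragment + 1, fragment))]
    index = ReferenceIndex([genome_b], k=15)
    identities = []
    for f in frags:
        best = None
        for a in map_reads([f], index, min_frag_identity, 50, mode="best_hit"):
            best = a
        if best is None:
            continue
        qs, qe = best.query_interval
        if qe - qs >= min_frag_coverage * len(f) and \
                best.pct_identity >= min_frag_identity:
            identities.append(best.pct_identity)
    if not identities:
        return float("nan"), 0.0
    return float(np.mean(identities)), len(identities) / len(frags)


def ani_symmetric(a: SeqRecord, b: SeqRecord, fragment: int = 1020) -> tuple[float, float]:
    """Mean of both directions; aligned fraction is the mean kept fraction."""
    ab, fab = ani(a, b, fragment)
    ba, fba = ani(b, a, fragment)
    vals = [v for v in (ab, ba) if not np.isnan(v)]
    if not vals:
        return float("nan"), 0.0
    return float(np.mean(vals)), float((fab + fba) / 2)


def dereplicate_genomes(genomes: list[SeqRecord], species_ani: float = 95.0,
                        min_aligned_fraction: float = 0.5,
                        fragment: int = 1020
                        ) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Greedy longest-first clustering at the species boundary: a genome
    joins the first representative with symmetric ANI >= species_ani over an
    aligned fraction >= min_aligned_fraction."""
    if not genomes:
        raise ValueError("no genomes")
    order = sorted(genomes, key=lambda g: (-len(g), g.id))
    reps: list[SeqRecord] = []
    clusters: dict[str, list[str]] = {}
    for g in order:
        home = None
        for rep in reps:
            val, frac = ani_symmetric(g, rep, fragment)
            if not np.isnan(val) and val >= species_ani and frac >= min_aligned_fraction:
                home = rep.id
                break
        if home is None:
            reps.append(g)
            clusters[g.id] = [g.id]
        else:
            clusters[home].append(g.id)
    return reps, clusters


# ---------------------------------------------------------------------------
# AAI / shared-protein network
# ---------------------------------------------------------------------------

_aligner: Align.PairwiseAligner | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        _aligner = Align.PairwiseAligner(
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-11.0, extend_gap_score=-1.0, mode="local")
    return _aligner


def _best_hits(qs: list[SeqRecord], ts: list[SeqRecord],
               min_identity: float, min_coverage: float) -> dict[str, tuple[str, float]]:
    """query id -> (best target id, pct identity).  A hit is valid when the
    local alignment covers >= min_coverage of the query and its identity is
    >= min_identity — coverage gating keeps short random local alignments
    from counting as orthologs."""
    aligner = _protein_aligner()
    out = {}
    for q in qs:
        best = None
        for t in ts:
            try:
                alns = aligner.align(q.seq, t.seq)
                aln = alns[0]
                score = alns.score
            except (IndexError, ValueError):
                continue
            counts = aln.counts()
            cols = aln.length
            if cols == 0:
                continue
            identity = 100.0 * counts.identities / cols
            qcov = (aln.aligned[0][-1][1] - aln.aligned[0][0][0]) / len(q.seq)
            if qcov < min_coverage or identity < min_identity:
                continue
            key = (score, identity, t.id)
            if best is None or key > best[0]:
                best = (key, t.id, identity)
        if best is not None:
            out[q.id] = (best[1], best[2])
    return out


def proteome_pair(name_a: str, prots_a: list[SeqRecord],
                  name_b: str, prots_b: list[SeqRecord],
                  min_hit_identity: float = 30.0,
                  min_hit_coverage: float = 0.5) -> ProteomePair:
    ab = _best_hits(prots_a, prots_b, min_hit_identity, min_hit_coverage)
    ba = _best_hits(prots_b, prots_a, min_hit_identity, min_hit_coverage)
    rbh = []
    for qa, (tb, ident) in ab.items():
        back = ba.get(tb)
        if back is not None and back[0] == qa:
            rbh.append((ident + back[1]) / 2)
    n = len(rbh)
    aai = float(np.mean(rbh)) if rbh else 0.0
    of = n / min(len(prots_a), len(prots_b)) if prots_a and prots_b else 0.0
    return ProteomePair(name_a, name_b, n, aai, of)


def aai_network(proteomes: dict[str, list[SeqRecord]],
                min_of: float = 0.25, min_aai: float = 30.0) -> list[ProteomePair]:
    """All-vs-all reciprocal-best-hit AAI; edges failing either floor (<25%
    shared proteins or <30% AAI) are removed.  Empty proteomes are excluded
    with a warning."""
    names = []
    for name in sorted(proteomes):
        if not proteomes[name]:
            import warnings
            warnings.warn(f"empty proteome {name!r} excluded from AAI network")
            continue
        names.append(name)
    edges = []
    for a, b in combinations(names, 2):
        pair = proteome_pair(a, proteomes[a], b, proteomes[b])
        if pair.of >= min_of and pair.aai >= min_aai:
            edges.append(pair)
    return edges


def network_to_table(edges: list[ProteomePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(genome_a=e.genome_a, genome_b=e.genome_b, n_rbh=e.n_rbh,
              aai=round(e.aai, 2), of=round(e.of, 4)) for e in edges],
        columns=["genome_a", "genome_b", "n_rbh", "aai", "of"])


def read_bed_mask(path) -> dict[str, list[tuple[int, int]]]:
    """BED (0-based half-open) -> per-sequence mask intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split()[:3]
            out.setdefault(chrom, []).append((int(s), int(e)))
    return out
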