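"""Seed-and-extend local alignment with explicit identity/length contracts.

This is the single engine behind fragment recruitment, coverage, read
clustering, scaffolding and circularity checks.  Alignment identity is
defined as matches / alignment columns with gap columns counted — the
convention all the thresholds in this package (95/50, 99/50, 99/1000,
97-removal, 80/50, 95/250) assume.

Algorithm: exact k-mer seeds (k = 15 for >=90% identity contracts, k = 11
below) located through a hash index of the references; seed hits are grouped
into diagonal bands; each band is extended with a banded edit-distance
alignment (edlib) of the read region against the implied reference window;
the resulting semi-global path is then trimmed to its maximum-scoring local
sub-path (match +1, mismatch/gap column -2), which converts the edit-distance
path into a proper local alignment.  Coordinates are 0-based half-open
internally; exported tables are 1-based inclusive and say so in their headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .records import SeqRecord, reverse_complement
from .seqstats import kmer_ids

_CIG_RE = re.compile(r"(\d+)([=XID])")

MATCH_SCORE = 1
MISMATCH_PENALTY = 2   # also per gap column, for local trimming / flat score


@dataclass
class LocalAlignment:
    """A scored local pairwise match."""

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]      # 0-based half-open, query forward coords
    subject_interval: tuple[int, int]    # 0-based half-open, subject forward coords
    strand: str                          # '+' | '-'
    matches: int
    aln_len: int                         # alignment columns incl. gap columns
    mismatches: int = 0
    gap_columns: int = 0
    gap_opens: int = 0

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.matches / self.aln_len if self.aln_len else 0.0

    @property
    def score(self) -> int:
        return MATCH_SCORE * self.matches - MISMATCH_PENALTY * (self.aln_len - self.matches)

    def gapped_score(self, match: int = 1, mismatch: int = 2,
                     gap_open: int = 5, gap_extend: int = 2) -> int:
        """Affine-gap score of the alignment path (for E-value statistics)."""
        return (match * self.matches - mismatch * self.mismatches
                - self.gap_opens * gap_open
                - (self.gap_columns - self.gap_opens) * gap_extend)


@dataclass
class Overlap:
    """A dovetail (suffix-prefix) or containment relation between two reads."""

    a_id: str
    b_id: str
    kind: str            # 'a_to_b' | 'b_to_a' | 'a_in_b' | 'b_in_a'
    alignment: LocalAlignment


# ---------------------------------------------------------------------------
# cigar handling and local trimming
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIG_RE.findall(cigar)]


def _trim_local(runs: list[tuple[str, int]]) -> tuple[int, int, list[tuple[str, int]]] | None:
    """Maximum-scoring contiguous sub-path of an alignment (run-level Kadane).

    Homogeneous runs mean the optimal window begins and ends on full '='
    runs, so whole-run Kadane is exact.  Returns (first_run, last_run, runs)
    or None when no positive-scoring window exists.
    """
    best = (0, -1, -1)  # score, start, end
    cur = 0
    cur_start = 0
    for i, (op, n) in enumerate(runs):
        s = MATCH_SCORE * n if op == "=" else -MISMATCH_PENALTY * n
        if cur <= 0:
            cur = s
            cur_start = i
        else:
            cur += s
        if cur > best[0]:
            best = (cur, cur_start, i)
    if best[1] < 0:
        return None
    i0, i1 = best[1], best[2]
    # never start or end on a non-match run
    while i0 <= i1 and runs[i0][0] != "=":
        i0 += 1
    while i1 >= i0 and runs[i1][0] != "=":
        i1 -= 1
    if i1 < i0:
        return None
    return i0, i1, runs


_Q_CONSUME = {"=": 1, "X": 1, "I": 1, "D": 0}
_T_CONSUME = {"=": 1, "X": 1, "I": 0, "D": 1}


def _path_stats(runs: list[tuple[str, int]], i0: int, i1: int) -> dict:
    q_pre = sum(n * _Q_CONSUME[op] for op, n in runs[:i0])
    t_pre = sum(n * _T_CONSUME[op] for op, n in runs[:i0])
    matches = mism = gaps = opens = qspan = tspan = 0
    for op, n in runs[i0:i1 + 1]:
        if op == "=":
            matches += n
        elif op == "X":
            mism += n
        else:
            gaps += n
            opens += 1
        qspan += n * _Q_CONSUME[op]
        tspan += n * _T_CONSUME[op]
    return dict(q_off=q_pre, t_off=t_pre, q_span=qspan, t_span=tspan,
                matches=matches, mismatches=mism, gap_columns=gaps,
                gap_opens=opens, aln_len=matches + mism + gaps)


# ---------------------------------------------------------------------------
# reference index
# ---------------------------------------------------------------------------

class ReferenceIndex:
    """Hash index of reference k-mers -> (reference, position) lists."""

    def __init__(self, references: list[SeqRecord], k: int = 15):
        if not references:
            raise ValueError("empty reference set")
        self.k = k
        self.refs = list(references)
        self.by_id = {r.id: r for r in references}
        self.table: dict[int, list[tuple[int, int]]] = {}
        for ri, ref in enumerate(self.refs):
            self._index_one(ri, ref)

    def _index_one(self, ri: int, ref: SeqRecord) -> None:
        ids = kmer_ids(ref.seq, self.k)
        table = self.table
        for pos, kid in enumerate(ids.tolist()):
            entry = table.get(kid)
            if entry is None:
                table[kid] = [(ri, pos)]
            else:
                entry.append((ri, pos))

    def add(self, ref: SeqRecord) -> None:
        self.refs.append(ref)
        self.by_id[ref.id] = ref
        self._index_one(len(self.refs) - 1, ref)


def _seed_hits(index: ReferenceIndex, seq: str, stride: int) -> list[tuple[int, int, int]]:
    """(ref_idx, qpos, tpos) for sampled query k-mers found in the index."""
    ids = kmer_ids(seq, index.k)
    hits = []
    table = index.table
    for q in range(0, len(ids), stride):
        entry = table.get(int(ids[q]))
        if entry:
            for ri, t in entry:
                hits.append((ri, q, t))
    return hits


def _cluster_hits(hits: list[tuple[int, int, int]], band: int,
                  min_seeds: int) -> list[tuple[int, list[tuple[int, int]]]]:
    """Group seed hits by reference and diagonal band -> (ref_idx, [(q, t)...])."""
    hits = sorted(hits, key=lambda h: (h[0], h[2] - h[1], h[2]))
    clusters = []
    cur_ref, cur_diag, cur = None, None, []
    for ri, q, t in hits:
        d = t - q
        if cur_ref != ri or cur_diag is None or d - cur_diag > band:
            if len(cur) >= min_seeds:
                clusters.append((cur_ref, cur))
            cur_ref, cur = ri, []
        cur.append((q, t))
        cur_diag = d
    if len(cur) >= min_seeds:
        clusters.append((cur_ref, cur))
    return clusters


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------

def _extend_cluster(query: str, ref_seq: str, seeds: list[tuple[int, int]],
                    min_identity: float, k: int) -> dict | None:
    qlen = len(query)
    qmin = min(q for q, _ in seeds)
    qmax = max(q for q, _ in seeds) + k
    dmin = min(t - q for q, t in seeds)
    dmax = max(t - q for q, t in seeds)
    err = 1.0 - min_identity / 100.0
    pad = int(err * qlen * 1.25) + 30
    q_lo = max(0, qmin - pad)
    q_hi = min(qlen, qmax + pad)
    w_lo = max(0, dmin + q_lo - pad)
    w_hi = min(len(ref_seq), dmax + q_hi + pad)
    if w_hi <= w_lo:
        return None
    # when the window is clipped at the reference bounds, clip the query
    # region to the positions reachable within the seed diagonals, or HW
    # (whole-query) alignment cannot fit
    q_lo = max(q_lo, w_lo - dmax)
    q_hi = min(q_hi, w_hi - dmin)
    if q_hi - q_lo < k:
        return None
    region = query[q_lo:q_hi]
    window = ref_seq[w_lo:w_hi]
    max_ed = int(err * len(region) * 1.5) + 16
    res = edlib.align(region, window, mode="HW", task="path", k=max_ed)
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start = res["locations"][0][0]
    runs = _parse_cigar(res["cigar"])
    trimmed = _trim_local(runs)
    if trimmed is None:
        return None
    i0, i1, runs = trimmed
    st = _path_stats(runs, i0, i1)
    qs = q_lo + st["q_off"]
    qe = qs + st["q_span"]
    ss = w_lo + t_start + st["t_off"]
    se = ss + st["t_span"]
    return dict(qs=qs, qe=qe, ss=ss, se=se, **{k2: st[k2] for k2 in
                ("matches", "mismatches", "gap_columns", "gap_opens", "aln_len")})


def _seed_params(min_identity: float, min_aln_len: int,
                 seed_k: int | None) -> tuple[int, int, int]:
    k = seed_k if seed_k is not None else (15 if min_identity >= 90 else 11)
    stride = int(np.clip((min_aln_len - k) // 3 if min_aln_len > k else 1, 1, 64))
    min_seeds = 1 if k >= 13 else 2
    return k, stride, min_seeds


def map_reads(reads: list[SeqRecord], references: list[SeqRecord] | ReferenceIndex,
              min_identity: float, min_aln_len: int,
              mode: str = "best_hit", seed_k: int | None = None) -> list[LocalAlignment]:
    """Map reads against references; report alignments meeting BOTH thresholds.

    ``best_hit`` keeps one alignment per read: highest score, ties broken by
    higher identity, then lexicographically smallest subject id, then smallest
    subject start.  Both strands are searched.  Reads shorter than
    ``min_aln_len`` are unmapped (not an error).
    """
    if mode not in ("best_hit", "all_hits"):
        raise ValueError(f"unknown mode {mode!r}")
    if min_identity <= 0 or min_aln_len <= 0:
        raise ValueError("thresholds must be positive")
    k, stride, min_seeds = _seed_params(min_identity, min_aln_len, seed_k)
    index = references if isinstance(references, ReferenceIndex) \
        else ReferenceIndex(references, k=k)
    out: list[LocalAlignment] = []
    for read in reads:
        if len(read) < min_aln_len:
            continue
        hits = _hits_for_sequence(read, index, min_identity, min_aln_len,
                                  stride, min_seeds)
        if not hits:
            continue
        if mode == "best_hit":
            hits.sort(key=lambda a: (-a.score, -a.pct_identity, a.subject_id,
                                     a.subject_interval[0]))
            out.append(hits[0])
        else:
            out.extend(hits)
    return out


def _hits_for_sequence(read: SeqRecord, index: ReferenceIndex,
                       min_identity: float, min_aln_len: int,
                       stride: int, min_seeds: int) -> list[LocalAlignment]:
    qlen = len(read)
    err = 1.0 - min_identity / 100.0
    band = max(64, int(2 * err * qlen) + 32)
    found: list[LocalAlignment] = []
    for strand in "+-":
        seq = read.seq if strand == "+" else reverse_complement(read.seq)
        clusters = _cluster_hits(_seed_hits(index, seq, stride), band, min_seeds)
        for ri, seeds in clusters:
            ref = index.refs[ri]
            ext = _extend_cluster(seq, ref.seq, seeds, min_identity, index.k)
            if ext is None or ext["aln_len"] < min_aln_len:
                continue
            identity = 100.0 * ext["matches"] / ext["aln_len"]
            if identity < min_identity:
                continue
            qs, qe = ext["qs"], ext["qe"]
            if strand == "-":
                qs, qe = qlen - ext["qe"], qlen - ext["qs"]
            found.append(LocalAlignment(
                read.id, ref.id, (qs, qe), (ext["ss"], ext["se"]), strand,
                ext["matches"], ext["aln_len"], ext["mismatches"],
                ext["gap_columns"], ext["gap_opens"]))
    return _dedupe(found)


def _dedupe(alns: list[LocalAlignment]) -> list[LocalAlignment]:
    """Drop alignments mostly contained in a higher-scoring one on both axes."""
    alns = sorted(alns, key=lambda a: (-a.score, a.subject_id,
                                       a.subject_interval[0], a.strand))
    kept: list[LocalAlignment] = []
    for a in alns:
        redundant = False
        for b in kept:
            if a.subject_id != b.subject_id or a.strand != b.strand:
                continue
            if _contained(a.query_interval, b.query_interval) and \
               _contained(a.subject_interval, b.subject_interval):
                redundant = True
                break
        if not redundant:
            kept.append(a)
    return kept


def _contained(inner: tuple[int, int], outer: tuple[int, int],
               frac: float = 0.8) -> bool:
    lo = max(inner[0], outer[0])
    hi = min(inner[1], outer[1])
    span = inner[1] - inner[0]
    return span > 0 and (hi - lo) >= frac * span


def align_pair(a: SeqRecord, b: SeqRecord, min_identity: float,
               min_len: int, seed_k: int | None = None) -> list[LocalAlignment]:
    """All maximal local alignments between two sequences (a = query)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sequence")
    k, stride, min_seeds = _seed_params(min_identity, min_len, seed_k)
    index = ReferenceIndex([b], k=k)
    hits = _hits_for_sequence(a, index, min_identity, min_len, stride, min_seeds)
    hits.sort(key=lambda h: (h.subject_interval[0], h.query_interval[0], h.strand))
    return hits


def end_overlap(a: SeqRecord, b: SeqRecord, min_identity: float = 99.0,
                min_len: int = 1000, max_overhang: int = 20) -> Overlap | None:
    """Dovetail overlap (suffix of one onto prefix of the other, either
    strand) meeting the thresholds, with <= max_overhang unaligned bases
    tolerated at the joined ends; containments are reported as such."""
    if len(a) < min_len or len(b) < min_len:
        return None
    la, lb = len(a), len(b)
    t = max_overhang
    best: Overlap | None = None
    for aln in align_pair(a, b, min_identity, min_len):
        (qs, qe), (ss, se) = aln.query_interval, aln.subject_interval
        kind = None
        if qs <= t and qe >= la - t:
            kind = "a_in_b"
        elif ss <= t and se >= lb - t:
            kind = "b_in_a"
        elif aln.strand == "+":
            if qe >= la - t and ss <= t:
                kind = "a_to_b"
            elif qs <= t and se >= lb - t:
                kind = "b_to_a"
        else:
            # on '-' strand, b's prefix in its forward coords is RC of its
            # suffix as aligned: suffix(a) ~ suffix(b) means a->rc(b)
            if qe >= la - t and se >= lb - t:
                kind = "a_to_b"
            elif qs <= t and ss <= t:
                kind = "b_to_a"
        if kind and (best is None or aln.score > best.alignment.score):
            best = Overlap(a.id, b.id, kind, aln)
    return best


# ---------------------------------------------------------------------------
# tabular export (BLAST outfmt-6-compatible columns)
# ---------------------------------------------------------------------------

def alignments_to_table(alns: list[LocalAlignment]):
    """DataFrame with outfmt-6-style columns; coordinates 1-based inclusive."""
    import pandas as pd
    rows = []
    for a in alns:
        qs, qe = a.query_interval
        ss, se = a.subject_interval
        if a.strand == "+":
            sstart, send = ss + 1, se
        else:
            sstart, send = se, ss + 1
        rows.append(dict(qseqid=a.query_id, sseqid=a.subject_id,
                         pident=round(a.pct_identity, 3), length=a.aln_len,
                         mismatch=a.mismatches, gapopen=a.gap_opens,
                         qstart=qs + 1, qend=qe, sstart=sstart, send=send,
                         score=a.score))
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "pident", "length",
                                       "mismatch", "gapopen", "qstart", "qend",
                                       "sstart", "send", "score"])
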