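"""Marker-gene (16S-like) extraction, validation, classification and profiles.

Candidate detection aligns each sequence against a marker reference set and
gates on a Karlin-Altschul E-value (E = K*m*n*exp(-lambda*S), database length
m) at E < 1e-5 — a deliberately permissive screen.  Validation requires the
alignment to cover a minimum fraction of the best reference (default 0.5),
standing in for a covariance-model check.  Classification assigns the
best-identity reference's taxonomy subject to read-class thresholds: short
reads need >=80% identity over >=90 aligned bases; long segments must be
>=1000 bases (and >=80% identity).  Dereplication clusters segments greedily,
longest first, at 97% identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mapping import LocalAlignment, align_pair
from .records import SeqRecord, reverse_complement

UNCLASSIFIED = "unclassified"

# ungapped scoring scheme behind the E-value statistics
_MATCH, _MISMATCH = 1, 2
_GAP_OPEN, _GAP_EXTEND = 5, 2
_KA_K = 0.3   # scale constant; the 1e-5 gate is screening, precision immaterial


@dataclass
class MarkerHit:
    source_id: str
    segment: SeqRecord              # extracted subsequence, reference orientation
    source_interval: tuple[int, int]
    strand: str
    best_ref: str
    evalue: float
    pct_identity: float
    aln_len: int
    taxon_path: tuple[str, ...] | None = None
    alignment: LocalAlignment | None = None


@dataclass
class TaxonProfile:
    level: int                       # rank depth (0-based index into taxon paths)
    counts: dict[str, int]
    fractions: dict[str, float]
    display: dict[str, float]        # groups <= min_display_fraction pooled as 'other'
    n_total: int


@lru_cache(maxsize=1)
def karlin_lambda() -> float:
    """lambda for the +1/-2 scheme under uniform base composition:
    solves sum_ij p_i p_j exp(lambda * s_ij) = 1."""
    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * _MATCH) + 0.75 * np.exp(-lam * _MISMATCH) - 1.0
    return brentq(f, 1e-6, 5.0)


def evalue(score: float, query_len: int, db_len: int) -> float:
    return float(_KA_K * query_len * db_len * np.exp(-karlin_lambda() * score))


def find_marker_candidates(seqs: list[SeqRecord], marker_refs: list[SeqRecord],
                           max_evalue: float = 1e-5,
                           min_identity: float = 70.0) -> list[MarkerHit]:
    """Best marker-matching segment per sequence with E < max_evalue.

    The extracted segment is reported in reference orientation (reverse
    complemented when the marker lies on the '-' strand of the source).
    """
    if not marker_refs:
        raise ValueError("empty marker reference set")
    db_len = sum(len(r) for r in marker_refs)
    hits: list[MarkerHit] = []
    for seq in seqs:
        best: tuple[float, LocalAlignment, SeqRecord] | None = None
        for ref in marker_refs:
            for aln in align_pair(ref, seq, min_identity, 30, seed_k=11):
                s = aln.gapped_score(_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXTEND)
                e = evalue(s, len(ref), db_len)
                if e < max_evalue and (best is None or e < best[0]):
                    best = (e, aln, ref)
        if best is None:
            continue
        e, aln, ref = best
        ss, se = aln.subject_interval     # interval on the source sequence
        segment = seq.seq[ss:se]
        if aln.strand == "-":
            segment = reverse_complement(segment)
        hits.append(MarkerHit(
            source_id=seq.id,
            segment=SeqRecord(f"{seq.id}|marker", segment),
            source_interval=(ss, se), strand=aln.strand,
            best_ref=ref.id, evalue=e, pct_identity=aln.pct_identity,
            aln_len=aln.aln_len, alignment=aln))
    return hits


def validate_marker(hit: MarkerHit, marker_refs: list[SeqRecord] | dict[str, SeqRecord],
                    min_model_fraction: float = 0.5) -> bool:
    """True iff the hit covers >= min_model_fraction of its best reference."""
    refs = marker_refs if isinstance(marker_refs, dict) \
        else {r.id: r for r in marker_refs}
    ref = refs[hit.best_ref]
    if hit.alignment is not None:
        qs, qe = hit.alignment.query_interval
        covered = qe - qs
    else:
        covered = len(hit.segment)
    return covered >= min_model_fraction * len(ref)


def _taxonomy_of(ref: SeqRecord) -> tuple[str, ...]:
    tax = ref.meta.get("taxonomy", "")
    return tuple(t.strip() for t in tax.split(";") if t.strip())


def classify_marker(hit: MarkerHit, taxonomy_refs: list[SeqRecord],
                    read_class: str,
                    min_identity: float = 80.0,
                    short_min_aln: int = 90,
                    long_min_segment: int = 1000) -> tuple[str, ...] | str:
    """Assign the best-identity reference's taxonomy, or UNCLASSIFIED.

    short class: >=80% identity AND >=90 aligned bases.
    long class: segment >=1000 bases AND >=80% identity.
    """
    if read_class not in ("short", "long"):
        raise ValueError(f"unknown read_class {read_class!r}")
    best: tuple[float, int, SeqRecord] | None = None
    for ref in taxonomy_refs:
        alns = align_pair(hit.segment, ref, min_identity * 0.8, 30, seed_k=11)
        for aln in alns:
            key = (aln.pct_identity, aln.aln_len)
            if best is None or key > (best[0], best[1]):
                best = (aln.pct_identity, aln.aln_len, ref)
    if best is None:
        return UNCLASSIFIED
    identity, aln_len, ref = best
    if read_class == "short":
        if identity >= min_identity and aln_len >= short_min_aln:
            return _taxonomy_of(ref)
    else:
        if len(hit.segment) >= long_min_segment and identity >= min_identity:
            return _taxonomy_of(ref)
    return UNCLASSIFIED


def dereplicate_markers(segments: list[SeqRecord], identity: float = 97.0,
                        min_self_coverage: float = 0.9
                        ) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Greedy longest-first clustering at >=identity over >=90% of the
    candidate's own length.  Returns (representatives, membership)."""
    order = sorted(segments, key=lambda s: (-len(s), s.id))
    reps: list[SeqRecord] = []
    members: dict[str, list[str]] = {}
    for seg in order:
        home = None
        for rep in reps:
            for aln in align_pair(seg, rep, identity, 50):
                qs, qe = aln.query_interval
                if qe - qs >= min_self_coverage * len(seg):
                    home = rep.id
                    break
            if home:
                break
        if home is None:
            reps.append(seg)
            members[seg.id] = [seg.id]
        else:
            members[home].append(seg.id)
    return reps, members


def taxon_profile(classified: list[tuple[str, ...] | str], level: int,
                  min_display_fraction: float = 0.01) -> TaxonProfile:
    """Aggregate taxon paths at a rank; pool groups <= the display floor
    ('larger than' is strict) into 'other' in the display table only."""
    counts: dict[str, int] = {}
    for path in classified:
        if path == UNCLASSIFIED or path is None:
            continue
        label = path[level] if level < len(path) else path[-1]
        counts[label] = counts.get(label, 0) + 1
    n_total = sum(counts.values())
    fractions = {t: c / n_total for t, c in counts.items()} if n_total else {}
    display: dict[str, float] = {}
    other = 0.0
    for t, f in sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0])):
        if f > min_display_fraction:
            display[t] = f
        else:
            other += f
    if other > 0:
        display["other"] = other
    return TaxonProfile(level, counts, fractions, display, n_total)


# ---------------------------------------------------------------------------
# I/O: marker FASTA with semicolon-delimited taxonomy in headers
# ---------------------------------------------------------------------------

def read_marker_fasta(path: str | Path) -> list[SeqRecord]:
    from Bio import SeqIO
    recs = []
    for r in SeqIO.parse(str(path), "fasta"):
        parts = r.description.split(None, 1)
        tax = parts[1].strip() if len(parts) > 1 else ""
        recs.append(SeqRecord(r.id, str(r.seq).upper(), meta={"taxonomy": tax}))
    return recs


def write_marker_fasta(refs: list[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            tax = r.meta.get("taxonomy", "")
            fh.write(f">{r.id} {tax}\n{r.seq}\n")


def hits_to_table(hits: list[MarkerHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        tax = ";".join(h.taxon_path) if isinstance(h.taxon_path, tuple) \
            else (h.taxon_path or "")
        rows.append(dict(source_id=h.source_id, start=h.source_interval[0] + 1,
                         end=h.source_interval[1], strand=h.strand,
                         best_ref=h.best_ref, evalue=h.evalue,
                         pct_identity=round(h.pct_identity, 2),
                         aln_len=h.aln_len, taxonomy=tax))
    return pd.DataFrame(rows, columns=["source_id", "start", "end", "strand",
                                       "best_ref", "evalue", "pct_identity",
                                       "aln_len", "taxonomy"])
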