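"""Assembly QC: circularity evidence, marker-set completeness, genome filters.

Circularity of a single-contig genome (LAG) is accepted when an independent
contig aligns >= 250 bp at >= 95% identity to BOTH sequence ends in a
junction-consistent way — the contig continues off the right end directly
onto the left end, which is only possible if the LAG is a linearized circle —
or when the LAG's own termini carry a direct repeat of at least that size
(the assembler-style circularity signal, reported separately).

Completeness/contamination follow the single-copy marker convention:
completeness = % of the marker set present at all, contamination = % of the
marker set present more than once.  The marker list is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mapping import LocalAlignment, align_pair
from .records import SeqRecord


@dataclass
class CircularityEvidence:
    lag_id: str
    supporting_contig: str | None
    left_end_aln: LocalAlignment | None
    right_end_aln: LocalAlignment | None
    self_terminal_repeat: LocalAlignment | None
    verdict: str                      # 'circular' | 'linear' | 'ambiguous'
    flagged: str | None = None


@dataclass
class MarkerSetResult:
    genome_id: str
    completeness: float               # percent of marker set present
    contamination: float              # percent of marker set duplicated
    present_markers: list[str]
    duplicated_markers: list[str]


# ---------------------------------------------------------------------------
# circularity
# ---------------------------------------------------------------------------

def check_circular(lag: SeqRecord, independent_contigs: list[SeqRecord],
                   min_identity: float = 95.0, min_end_aln: int = 250,
                   window_factor: int = 2) -> CircularityEvidence:
    """Junction evidence for a linearized-circle LAG.

    A supporting contig must align >= min_end_aln bases within the terminal
    window (window_factor x min_end_aln bases) of BOTH ends, reaching the
    respective terminus, with the two matches adjacent on the contig in
    junction order (right end first, then left end) and on one strand.
    """
    if len(lag) <= 2 * min_end_aln:
        raise ValueError("LAG shorter than twice the end-alignment floor")
    w = window_factor * min_end_aln
    w = min(w, len(lag) // 2)
    left = SeqRecord(f"{lag.id}|L", lag.seq[:w])
    right = SeqRecord(f"{lag.id}|R", lag.seq[-w:])

    # self terminal repeat: direct repeat shared by the two termini
    self_rep = None
    for aln in align_pair(left, right, min_identity, min_end_aln):
        if aln.strand != "+":
            continue
        (qs, _qe), (_ss, se) = aln.query_interval, aln.subject_interval
        if qs <= 20 and se >= w - 20:   # anchored at the extreme termini
            if self_rep is None or aln.score > self_rep.score:
                self_rep = aln

    slack = 50
    best: tuple[str, LocalAlignment, LocalAlignment] | None = None
    conflict = False
    for contig in independent_contigs:
        lefts = [a for a in align_pair(contig, left, min_identity, min_end_aln)
                 if a.subject_interval[0] <= 20]          # reaches the 5' terminus
        rights = [a for a in align_pair(contig, right, min_identity, min_end_aln)
                  if a.subject_interval[1] >= w - 20]      # reaches the 3' terminus
        for la in lefts:
            for ra in rights:
                if la.strand != ra.strand:
                    continue
                lq, rq = la.query_interval, ra.query_interval
                if la.strand == "+":
                    junction_ok = 0 <= lq[0] - rq[1] <= slack
                else:
                    junction_ok = 0 <= rq[0] - lq[1] <= slack
                if junction_ok:
                    if best is None or la.score + ra.score > \
                            best[1].score + best[2].score:
                        best = (contig.id, la, ra)
        if (lefts or rights) and not best:
            # end hits exist but never combine consistently
            if lefts and rights:
                conflict = True

    if best is not None:
        return CircularityEvidence(lag.id, best[0], best[1], best[2],
                                   self_rep, "circular")
    if self_rep is not None:
        return CircularityEvidence(lag.id, None, None, None, self_rep, "circular")
    if conflict:
        return CircularityEvidence(lag.id, None, None, None, None, "ambiguous")
    flagged = "no-independent-contigs" if not independent_contigs else None
    return CircularityEvidence(lag.id, None, None, None, None, "linear",
                               flagged=flagged)


# ---------------------------------------------------------------------------
# marker completeness / contamination
# ---------------------------------------------------------------------------

def marker_completeness(gene_markers: list[str] | pd.DataFrame,
                        marker_set: list[str],
                        genome_id: str = "genome") -> MarkerSetResult:
    """Count marker labels against a pluggable single-copy marker list."""
    if not marker_set:
        raise ValueError("empty marker set")
    if isinstance(gene_markers, pd.DataFrame):
        labels = [m for m in gene_markers.get("marker", []) if isinstance(m, str)]
    else:
        labels = [m for m in gene_markers if m]
    counts: dict[str, int] = {}
    marker_lookup = set(marker_set)
    for m in labels:
        if m in marker_lookup:
            counts[m] = counts.get(m, 0) + 1
    present = sorted(counts)
    duplicated = sorted(m for m, c in counts.items() if c > 1)
    n = len(marker_set)
    return MarkerSetResult(genome_id,
                           100.0 * len(present) / n,
                           100.0 * len(duplicated) / n,
                           present, duplicated)


def filter_genomes(results: list[MarkerSetResult],
                   min_completeness: float = 40.0,
                   max_contamination: float = 5.0) -> list[str]:
    """Keep iff completeness >= 40 AND contamination <= 5; the discard rule
    is strict ('completeness < 40%' / 'contamination > 5%'), so boundary
    values are kept."""
    return [r.genome_id for r in results
            if r.completeness >= min_completeness
            and r.contamination <= max_contamination]


def evidence_table(evidence: list[CircularityEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(lag_id=e.lag_id, verdict=e.verdict,
              supporting_contig=e.supporting_contig or "",
              self_terminal_repeat=bool(e.self_terminal_repeat),
              flagged=e.flagged or "") for e in evidence],
        columns=["lag_id", "verdict", "supporting_contig",
                 "self_terminal_repeat", "flagged"])
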