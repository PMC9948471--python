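"""Contig and long-read binning.

Two procedures live here.  Contig binning assigns contigs >= 5 kb a
phylum-level label when >= 50% of their genes share a best-hit taxonomy, then
clusters each taxonomy stratum on composition (tetranucleotide PCA + GC) and
differential coverage (z-scored log-RPKG across metagenomes), assigning
unclassified contigs to the nearest cluster within that cluster's internal
radius.  Seeded read binning removes reads matching known genomes at >=97%
identity, embeds the rest by trinucleotide composition (plus optional
per-read coverage), and grows clusters around marker-carrying seed reads.

The clustering surrogates here are deterministic; the original analysis was
human-curated, which cannot be tested.  RPKG = mapped reads per contig-kb per
metagenome-Gb, with the metagenome subsampled as a deterministic read-file
prefix for run-to-run reproducibility.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .mapping import ReferenceIndex, end_overlap, map_reads
from .records import SeqRecord, gc_fraction, reverse_complement
from .seqstats import composition_profile, pca

UNCLASSIFIED = "unclassified"
UNBINNED = "unbinned"


@dataclass
class BinAssignment:
    """Member -> bin labels plus per-bin summary statistics."""

    assignments: dict[str, str]
    summaries: pd.DataFrame | None = None
    bin_markers: dict[str, list[str]] = field(default_factory=dict)

    def members_of(self, label: str) -> list[str]:
        return [m for m, b in self.assignments.items() if b == label]

    @property
    def labels(self) -> list[str]:
        return sorted({b for b in self.assignments.values() if b != UNBINNED})


# ---------------------------------------------------------------------------
# taxonomy consensus
# ---------------------------------------------------------------------------

def classify_contig(contig_len: int, gene_labels: list[str | None],
                    min_len: int = 5000, min_fraction: float = 0.5) -> str:
    """Modal gene taxonomy if its fraction (over ALL genes, unlabeled
    included in the denominator) reaches min_fraction; contigs shorter than
    min_len, tied, or without genes are unclassified."""
    if contig_len < min_len or not gene_labels:
        return UNCLASSIFIED
    counts = Counter(lab for lab in gene_labels if lab is not None)
    if not counts:
        return UNCLASSIFIED
    n = len(gene_labels)
    ranked = counts.most_common()
    top_label, top = ranked[0]
    if top / n < min_fraction:
        return UNCLASSIFIED
    if len(ranked) > 1 and ranked[1][1] == top:
        return UNCLASSIFIED   # two labels meet the rule; cannot name one
    return top_label


def classify_contigs(contigs: list[SeqRecord], genes: pd.DataFrame,
                     min_len: int = 5000, min_fraction: float = 0.5) -> dict[str, str]:
    by_contig = defaultdict(list)
    for row in genes.itertuples():
        lab = row.best_hit_taxon
        if isinstance(lab, float) and np.isnan(lab):
            lab = None
        by_contig[row.contig_id].append(lab)
    return {c.id: classify_contig(len(c), by_contig.get(c.id, []),
                                  min_len, min_fraction)
            for c in contigs}


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def contig_coverage(contigs: list[SeqRecord],
                    metagenomes: dict[str, list[SeqRecord]],
                    min_identity: float = 99.0, min_aln: int = 50,
                    subsample: int | None = 20_000_000) -> pd.DataFrame:
    """RPKG matrix (contigs x metagenomes) from best-hit read mapping.

    The subsample is a deterministic prefix of each read set; the metagenome
    size used for normalization is the base count of that prefix.
    """
    if not metagenomes:
        raise ValueError("at least one metagenome required")
    for c in contigs:
        if len(c) == 0:
            raise ValueError(f"zero-length contig {c.id}")
    index = ReferenceIndex(contigs, k=15)
    data = {}
    for name, reads in metagenomes.items():
        use = reads if subsample is None else reads[:subsample]
        gb = sum(len(r) for r in use) / 1e9
        counts = Counter(a.subject_id for a in
                         map_reads(use, index, min_identity, min_aln, mode="best_hit"))
        data[name] = [counts.get(c.id, 0) / ((len(c) / 1e3) * gb) if gb > 0 else 0.0
                      for c in contigs]
    return pd.DataFrame(data, index=[c.id for c in contigs])


# ---------------------------------------------------------------------------
# contig binning
# ---------------------------------------------------------------------------

def _coverage_features(coverage: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    dropped = [c for c in coverage.columns if not coverage[c].any()]
    kept = [c for c in coverage.columns if c not in dropped]
    X = np.log10(coverage[kept].to_numpy(dtype=float) + 0.1)
    return X, dropped


def bin_contigs(contigs: list[SeqRecord], coverage: pd.DataFrame,
                taxonomy: dict[str, str], pca_dims: int = 3,
                eps: float = 1.0, eps_nn_factor: float = 2.5,
                min_samples: int = 2) -> BinAssignment:
    """Stratified density clustering on (tetra PCs, GC, z-scored log-RPKG).

    The DBSCAN radius within a stratum is max(eps, eps_nn_factor x median
    nearest-neighbour distance): within-genome neighbours sit much closer
    than contigs of different genomes in the whitened feature space, so the
    adaptive radius tracks the local noise scale and degrades gracefully
    when a stratum holds a single genome.  Unclassified contigs (and stratum
    noise points) join the nearest cluster whose distance is within that
    cluster's 95th-percentile internal radius, else stay unbinned.
    Deterministic.
    """
    ids = [c.id for c in contigs]
    if set(ids) - set(coverage.index) or set(ids) - set(taxonomy):
        raise ValueError("feature blocks must cover the same contig set")
    profiles = np.vstack([composition_profile(c, k=4).kmer_freq for c in contigs])
    pcs = pca(profiles, n_components=pca_dims).coordinates
    gc = np.array([gc_fraction(c.seq) for c in contigs])[:, None]
    cov, dropped = _coverage_features(coverage.loc[ids])
    if dropped:
        import warnings
        warnings.warn(f"metagenome(s) with no mapped reads dropped from features: {dropped}")
    X = np.hstack([pcs, gc, cov])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    strata = defaultdict(list)
    for i, cid in enumerate(ids):
        strata[taxonomy[cid]].append(i)

    labels = {cid: UNBINNED for cid in ids}
    clusters: list[tuple[str, np.ndarray]] = []   # (bin label, member row indices)
    n_bins = 0
    for taxon in sorted(strata):
        if taxon == UNCLASSIFIED:
            continue
        rows = np.array(strata[taxon])
        if len(rows) == 1:
            lab = f"bin{n_bins:03d}"
            n_bins += 1
            labels[ids[rows[0]]] = lab
            clusters.append((lab, rows))
            continue
        D = np.linalg.norm(X[rows][:, None] - X[rows][None, :], axis=2)
        np.fill_diagonal(D, np.inf)
        stratum_eps = max(eps, eps_nn_factor * float(np.median(D.min(axis=1))))
        db = DBSCAN(eps=stratum_eps,
                    min_samples=min(min_samples, len(rows))).fit(X[rows])
        for cl in sorted(set(db.labels_) - {-1}):
            members = rows[db.labels_ == cl]
            lab = f"bin{n_bins:03d}"
            n_bins += 1
            for i in members:
                labels[ids[i]] = lab
            clusters.append((lab, members))

    # attach unclassified / noise contigs to the nearest compatible cluster
    radii = []
    for lab, members in clusters:
        centroid = X[members].mean(axis=0)
        if len(members) > 1:
            d = np.linalg.norm(X[members] - centroid, axis=1)
            radius = float(np.percentile(d, 95))
        else:
            radius = 0.0
        radii.append((lab, centroid, max(radius, eps)))
    for i, cid in enumerate(ids):
        if labels[cid] != UNBINNED:
            continue
        best_lab, best_d = None, np.inf
        for lab, centroid, radius in radii:
            d = float(np.linalg.norm(X[i] - centroid))
            if d <= radius and d < best_d:
                best_lab, best_d = lab, d
        if best_lab is not None:
            labels[cid] = best_lab
    return BinAssignment(labels)


# ---------------------------------------------------------------------------
# seeded read binning
# ---------------------------------------------------------------------------

def seeded_read_binning(reads: list[SeqRecord], seed_read_ids: list[str],
                        known_genomes: list[SeqRecord] | None = None,
                        remove_identity: float = 97.0,
                        remove_coverage: float = 0.5,
                        pca_dims: int = 3,
                        coverage: dict[str, float] | None = None,
                        distance_gate: float = 2.5,
                        seed_merge_gate: float = 1.0,
                        n_refine: int = 3,
                        seed_markers: dict[str, str] | None = None) -> BinAssignment:
    """Cluster long reads around marker-carrying seed reads.

    1. discard reads aligning to known genomes at >= remove_identity over
       >= remove_coverage of their length;
    2. feature = trinucleotide-profile PCA (+ log-coverage when supplied),
       whitened;
    3. seeds within ``seed_merge_gate`` of each other merge (single linkage)
       into one cluster; every read joins its nearest seed-cluster centroid
       when within ``distance_gate``, else unbinned.  Both gates are
       distances in the whitened feature space, calibrated on synthetic
       populations (seeds of one population chain at < 1 while distinct
       populations stay > 1.4 apart at 2% internal divergence).

    After the initial nearest-seed assignment the cluster centroids are
    re-estimated from their members and reads re-assigned (``n_refine``
    deterministic iterations).  A single seed read is a noisy estimate of
    its population's composition centroid — in particular the embedded
    marker gene biases the seed read's own profile — and refinement washes
    that bias out.
    """
    seed_set = set(seed_read_ids)
    if not seed_set:
        raise ValueError("no seed reads given")
    missing = seed_set - {r.id for r in reads}
    if missing:
        raise ValueError(f"seed ids not in read set: {sorted(missing)[:3]}")

    removed: set[str] = set()
    if known_genomes:
        for aln in map_reads(reads, known_genomes, remove_identity, 50,
                             mode="best_hit"):
            qs, qe = aln.query_interval
            rlen = next(len(r) for r in reads if r.id == aln.query_id)
            if qe - qs >= remove_coverage * rlen:
                removed.add(aln.query_id)
    kept = [r for r in reads if r.id not in removed]
    kept_seeds = [s for s in seed_read_ids if s not in removed]
    if not kept_seeds:
        raise ValueError("all seed reads were removed as known-genome matches")

    profiles = np.vstack([composition_profile(r, k=3).kmer_freq for r in kept])
    feats = pca(profiles, n_components=pca_dims).coordinates
    if coverage is not None:
        cov = np.array([np.log10(coverage.get(r.id, 0.0) + 0.1) for r in kept])[:, None]
        feats = np.hstack([feats, cov])
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - mu) / sd

    idx = {r.id: i for i, r in enumerate(kept)}
    seed_rows = [idx[s] for s in kept_seeds]

    # union-find merge of seeds within the gate
    parent = list(range(len(seed_rows)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seed_rows)):
        for j in range(i + 1, len(seed_rows)):
            d = np.linalg.norm(feats[seed_rows[i]] - feats[seed_rows[j]])
            if d <= seed_merge_gate:
                parent[find(j)] = find(i)

    groups = defaultdict(list)
    for i, row in enumerate(seed_rows):
        groups[find(i)].append(row)
    bins = []
    for gi, rows in enumerate(sorted(groups.values(), key=lambda rs: min(rs))):
        centroid = feats[rows].mean(axis=0)
        bins.append((f"rbin{gi:02d}", rows, centroid))

    def assign(centroids: dict[str, np.ndarray]) -> dict[str, str]:
        out = {r.id: UNBINNED for r in reads}
        for r in kept:
            i = idx[r.id]
            best_lab, best_d = None, np.inf
            for lab, centroid in centroids.items():
                d = float(np.linalg.norm(feats[i] - centroid))
                if d <= distance_gate and d < best_d:
                    best_lab, best_d = lab, d
            if best_lab is not None:
                out[r.id] = best_lab
        return out

    centroids = {lab: centroid for lab, _rows, centroid in bins}
    assignments = assign(centroids)
    for _ in range(n_refine):
        new_centroids = {}
        for lab in centroids:
            rows = [idx[r.id] for r in kept if assignments[r.id] == lab]
            new_centroids[lab] = feats[rows].mean(axis=0) if rows else centroids[lab]
        new_assignments = assign(new_centroids)
        if new_assignments == assignments:
            break
        centroids, assignments = new_centroids, new_assignments

    bin_markers: dict[str, list[str]] = {}
    for lab, rows, _ in bins:
        sids = [kept[r].id for r in rows]
        if seed_markers:
            bin_markers[lab] = sorted({seed_markers.get(s, s) for s in sids})
        else:
            bin_markers[lab] = sorted(sids)
    return BinAssignment(assignments, bin_markers=bin_markers)


# ---------------------------------------------------------------------------
# redundancy removal (greedy incremental clustering, cd-hit -G 0 -aS 0.9
# -c 0.99 -g 1 semantics)
# ---------------------------------------------------------------------------

def remove_redundancy(reads: list[SeqRecord], identity: float = 99.0,
                      short_cov: float = 0.9
                      ) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Greedy longest-first: a read is redundant when a local alignment to an
    already-kept read reaches the identity threshold and covers >= short_cov
    of the shorter sequence; it is assigned to the best-matching kept read."""
    order = sorted(reads, key=lambda r: (-len(r), r.id))
    kept: list[SeqRecord] = []
    members: dict[str, list[str]] = {}
    index: ReferenceIndex | None = None
    for read in order:
        best: tuple[float, str] | None = None
        if index is not None:
            for aln in map_reads([read], index, identity, 50, mode="all_hits"):
                qs, qe = aln.query_interval
                shorter = min(len(read), len(index.by_id[aln.subject_id]))
                if qe - qs >= short_cov * shorter:
                    if best is None or aln.pct_identity > best[0]:
                        best = (aln.pct_identity, aln.subject_id)
        if best is None:
            kept.append(read)
            members[read.id] = [read.id]
            if index is None:
                index = ReferenceIndex([read], k=15)
            else:
                index.add(read)
        else:
            members[best[1]].append(read.id)
    return kept, members


# ---------------------------------------------------------------------------
# read-to-read scaffolding
# ---------------------------------------------------------------------------

def scaffold_bin(reads: list[SeqRecord], min_identity: float = 99.0,
                 min_overlap: int = 1000, max_overhang: int = 20) -> list[SeqRecord]:
    """Merge unambiguous dovetail paths into larger fragments.

    Builds an overlap graph over oriented reads from end-to-end alignments
    (>= min_identity over > min_overlap columns); simple paths whose internal
    nodes have exactly one incoming and one outgoing overlap are stitched by
    coordinates, the earlier read's base winning at disagreeing columns.
    Branching (fork) nodes are never merged across.  Containments are left as
    members of their container's path output.
    """
    if len(reads) <= 1:
        return list(reads)
    succ: dict[tuple[str, int], list[tuple[tuple[str, int], int]]] = defaultdict(list)
    pred: dict[tuple[str, int], list[tuple[str, int]]] = defaultdict(list)
    contained: set[str] = set()
    for i, a in enumerate(reads):
        for b in reads[i + 1:]:
            ov = end_overlap(a, b, min_identity, min_overlap, max_overhang)
            if ov is None:
                continue
            if ov.kind == "a_in_b":
                contained.add(a.id)
                continue
            if ov.kind == "b_in_a":
                contained.add(b.id)
                continue
            aln = ov.alignment
            olen = aln.aln_len
            flip = 0 if aln.strand == "+" else 1
            if ov.kind == "a_to_b":
                edges = [((a.id, 0), (b.id, flip), olen),
                         ((b.id, 1 - flip), (a.id, 1), olen)]
            else:
                edges = [((b.id, flip), (a.id, 0), olen),
                         ((a.id, 1), (b.id, 1 - flip), olen)]
            for u, v, w in edges:
                succ[u].append((v, w))
                pred[v].append(u)

    by_id = {r.id: r for r in reads}
    usable = [r.id for r in reads if r.id not in contained]
    merged: list[SeqRecord] = []
    used: set[str] = set()

    def oriented(rid: str, o: int) -> str:
        return by_id[rid].seq if o == 0 else reverse_complement(by_id[rid].seq)

    def unambiguous(node: tuple[str, int]) -> tuple[str, int] | None:
        nxt = [v for v, _ in succ.get(node, []) if v[0] not in contained]
        if len(nxt) != 1:
            return None
        v = nxt[0]
        prv = [u for u in pred.get(v, []) if u[0] not in contained]
        if len(prv) != 1:
            return None
        return v

    for rid in usable:
        if rid in used:
            continue
        # walk left to the path start
        node = (rid, 0)
        seen = {rid}
        while True:
            prv = [u for u in pred.get(node, []) if u[0] not in contained]
            if len(prv) != 1 or unambiguous(prv[0]) != node or prv[0][0] in seen:
                break
            node = prv[0]
            seen.add(node[0])
        # walk right, stitching
        path = [node]
        while True:
            nxt = unambiguous(path[-1])
            if nxt is None or nxt[0] in {p[0] for p in path}:
                break
            path.append(nxt)
        if any(p[0] in used for p in path):
            continue
        for p in path:
            used.add(p[0])
        if len(path) == 1:
            merged.append(by_id[rid])
            continue
        seq = oriented(*path[0])
        for (prev_node, cur_node) in zip(path, path[1:]):
            olen = next(w for v, w in succ[prev_node] if v == cur_node)
            nxt_seq = oriented(*cur_node)
            # first-read base wins: keep current seq, append the suffix
            overlap_cols = min(olen, len(nxt_seq))
            seq = seq + nxt_seq[overlap_cols:]
        name = "merge_" + "+".join(p[0] for p in path)
        merged.append(SeqRecord(name, seq,
                                meta={"members": [p[0] for p in path]}))
    return merged


# ---------------------------------------------------------------------------
# bin summaries
# ---------------------------------------------------------------------------

def bin_summary(members: list[SeqRecord], genes: pd.DataFrame | None = None,
                rpkg: dict[str, float] | None = None) -> dict:
    """Summary-statistics row: total size, GC mean +/- SD (percent,
    length-unweighted across members), gene count, mean gene size, RPKG."""
    if not members:
        raise ValueError("empty bin")
    gcs = np.array([100.0 * gc_fraction(m.seq) for m in members])
    row = {
        "total_size_bp": int(sum(len(m) for m in members)),
        "gc_mean_pct": float(gcs.mean()),
        "gc_sd_pct": float(gcs.std(ddof=1)) if len(gcs) > 1 else 0.0,
    }
    if genes is not None:
        ids = {m.id for m in members}
        sub = genes[genes.contig_id.isin(ids)]
        row["n_genes"] = int(len(sub))
        row["mean_gene_size_bp"] = float((sub.end - sub.start).mean()) if len(sub) \
            else float("nan")
    if rpkg:
        for name, value in rpkg.items():
            row[f"rpkg_{name}"] = value
    return row


def summarize_bins(assignment: BinAssignment, seqs: list[SeqRecord],
                   genes: pd.DataFrame | None = None) -> pd.DataFrame:
    by_id = {s.id: s for s in seqs}
    rows = {}
    for lab in assignment.labels:
        members = [by_id[m] for m in assignment.members_of(lab) if m in by_id]
        if members:
            rows[lab] = bin_summary(members, genes)
    return pd.DataFrame.from_dict(rows, orient="index")
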