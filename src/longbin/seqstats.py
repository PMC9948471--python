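"""Composition statistics and ordination.

GC content, k-mer frequency vectors (k = 3 or 4, optionally canonical, i.e.
strand-merged), PCA of composition profiles, Bray-Curtis dissimilarity and
principal-coordinates analysis.  These are the features behind contig binning
and whole-metagenome comparison.

k-mer counting skips every window containing an ambiguity code rather than
recoding it, to avoid composition bias.  Canonical counting merges each k-mer
with its reverse complement so that profiles of a sequence and its reverse
complement are identical — reads come off both strands, and this makes read
and contig profiles directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .records import SeqRecord, gc_fraction

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i


@dataclass
class CompositionProfile:
    seq_id: str
    length: int
    gc: float
    k: int
    canonical: bool
    kmer_freq: np.ndarray


@dataclass
class OrdinationResult:
    coordinates: np.ndarray        # n x d
    explained_fraction: np.ndarray  # length d, non-increasing
    method: str
    n_negative_eigs: int = 0


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _rc_map(k: int) -> np.ndarray:
    """id -> id of reverse complement, over 4**k k-mer codes."""
    n = 4 ** k
    ids = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        base = (ids >> (2 * (k - 1 - j))) & 3
        rc |= (3 - base) << (2 * j)
    return rc


@lru_cache(maxsize=8)
def canonical_index(k: int) -> tuple[np.ndarray, np.ndarray]:
    """(fold, keep): fold maps each k-mer id to its canonical slot index;
    keep lists the canonical k-mer ids in order."""
    rc = _rc_map(k)
    ids = np.arange(4 ** k)
    canon = np.minimum(ids, rc)
    keep = np.unique(canon)
    slot = np.searchsorted(keep, canon)
    return slot, keep


def kmer_ids(seq: str, k: int) -> np.ndarray:
    """ids of every valid (A/C/G/T-only) k-window, in order."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    valid = codes != 255
    vals = np.where(valid, codes, 0).astype(np.int64)
    ids = np.zeros(codes.size - k + 1, dtype=np.int64)
    ok = np.ones(codes.size - k + 1, dtype=bool)
    for j in range(k):
        ids = (ids << 2) | vals[j:codes.size - k + 1 + j]
        ok &= valid[j:codes.size - k + 1 + j]
    return ids[ok]


def kmer_counts(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    ids = kmer_ids(seq, k)
    counts = np.bincount(ids, minlength=4 ** k).astype(float)
    if canonical:
        slot, keep = canonical_index(k)
        folded = np.zeros(keep.size)
        np.add.at(folded, slot, counts)
        return folded
    return counts


def kmer_alphabet(k: int, canonical: bool = True) -> list[str]:
    """The k-mer labels matching the columns of kmer_counts."""
    def decode(i: int) -> str:
        return "".join("ACGT"[(i >> (2 * (k - 1 - j))) & 3] for j in range(k))
    if canonical:
        _, keep = canonical_index(k)
        return [decode(int(i)) for i in keep]
    return [decode(i) for i in range(4 ** k)]


def composition_profile(seq: SeqRecord | str, k: int = 4,
                        canonical: bool = True,
                        seq_id: str | None = None) -> CompositionProfile:
    """GC + normalized k-mer frequency vector of one sequence."""
    if k not in (3, 4):
        raise ValueError("k must be 3 or 4")
    if isinstance(seq, SeqRecord):
        seq_id = seq_id or seq.id
        s = seq.seq
    else:
        s = seq
        seq_id = seq_id or "seq"
    if len(s) == 0:
        raise ValueError("empty sequence")
    counts = kmer_counts(s, k, canonical)
    total = counts.sum()
    freq = counts / total if total > 0 else counts
    return CompositionProfile(seq_id, len(s), gc_fraction(s), k, canonical, freq)


def metagenome_kmer_profile(reads: list[SeqRecord], k: int = 4,
                            max_reads: int | None = None,
                            canonical: bool = True) -> np.ndarray:
    """Pooled k-mer frequency over a deterministic prefix of the read set."""
    if not reads:
        raise ValueError("empty read set")
    use = reads if max_reads is None else reads[:max_reads]
    pooled = None
    for r in use:
        c = kmer_counts(r.seq, k, canonical)
        pooled = c if pooled is None else pooled + c
    total = pooled.sum()
    return pooled / total if total > 0 else pooled


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def pca(profiles: np.ndarray, n_components: int | None = None) -> OrdinationResult:
    """PCA of frequency rows (no transform): centered SVD, components ordered
    by explained variance, sign fixed so each component's largest-magnitude
    loading is positive."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix of equal-length rows")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    total = var.sum()
    d = min(n - 1, p) if n_components is None else min(n_components, len(S))
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(d):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    coords = U[:, :d] * S[:d]
    explained = var[:d] / total if total > 0 else np.zeros(d)
    if total == 0:
        coords = np.zeros((n, d))
    return OrdinationResult(coords, explained, "pca")


def bray_curtis(p, q) -> float:
    """BC = sum|p_i - q_i| / sum(p_i + q_i) over non-negative vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("vectors must have equal dimension")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative entries")
    if p.sum() == 0 and q.sum() == 0:
        raise ValueError("both vectors all-zero")
    if np.array_equal(p, q):
        return 0.0
    return float(_scipy_braycurtis(p, q))


def pcoa(dissimilarity: np.ndarray, ids: list[str] | None = None) -> OrdinationResult:
    """Principal-coordinates analysis of a symmetric dissimilarity matrix.

    Classical double-centering of -D^2/2; only non-negative eigenpairs are
    kept, and the number of dropped negative eigenvalues is reported.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("diagonal must be zero")
    n = D.shape[0]
    if not D.any():
        return OrdinationResult(np.zeros((n, 1)), np.zeros(1), "pcoa")
    dm = DistanceMatrix(D, ids=ids or [f"s{i}" for i in range(n)])
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.values
    n_neg = int((eig < -1e-9 * max(abs(eig).max(), 1.0)).sum())
    keep = eig > 1e-9 * max(eig.max(), 1.0)
    coords = res.samples.values[:, keep]
    explained = res.proportion_explained.values[keep]
    # deterministic sign per axis
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return OrdinationResult(coords, explained, "pcoa", n_negative_eigs=n_neg)
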