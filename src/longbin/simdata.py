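"""Synthetic communities with complete ground truth.

This module generates the inputs the rest of the package analyses: genomes
with controlled GC and distinct tetranucleotide signatures, intra-population
strain clouds (the property that defeats assembly of hyper-diverse clades),
circular replicons, embedded marker genes, log-skewed abundance profiles, and
long/short read sets with per-read truth labels.

The background genome model is an order-3 Markov chain whose 64x4 transition
table is sampled from ``signature_seed`` and then exponentially tilted so that
the chain's stationary GC equals ``gc_target`` exactly.  Sampling the table per
genome gives each genome a distinct, stable tetranucleotide signature — the
feature the composition-based binners in this package rely on.

Population structure is modelled as independent per-strain substitution
(no indels), so every strain stays coordinate-aligned to its parent and exact
identities are computable for test oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .records import SeqRecord, gc_fraction, reverse_complement, write_fasta, write_fastq

BASES = "ACGT"
_GC_MASK = np.array([0.0, 1.0, 1.0, 0.0])  # A C G T


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Blueprint of one synthetic genome."""

    name: str
    length: int
    gc_target: float = 0.5
    signature_seed: int = 0
    circular: bool = False
    marker_template: str | None = None
    marker_divergence: float = 0.0

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome {self.name}: length must be positive, got {self.length}")
        if not 0.25 <= self.gc_target <= 0.75:
            raise ValueError(f"genome {self.name}: gc_target {self.gc_target} outside [0.25, 0.75]")
        if not 0.0 <= self.marker_divergence <= 0.3:
            raise ValueError("marker_divergence outside [0, 0.3]")
        if self.marker_template is not None and len(self.marker_template) >= self.length:
            raise ValueError("marker template longer than genome")


@dataclass
class CommunityMember:
    genome: GenomeSpec
    abundance: float
    population_divergence: float = 0.0
    n_strains: int = 1


@dataclass
class CommunitySpec:
    members: list[CommunityMember]
    rng_seed: int = 0

    def validate(self) -> None:
        total = sum(m.abundance for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {total}, expected 1")
        for m in self.members:
            m.genome.validate()
            if m.n_strains < 1:
                raise ValueError("n_strains must be >= 1")
            if not 0.0 <= m.population_divergence <= 0.05:
                raise ValueError("population_divergence outside [0, 0.05]")


@dataclass
class ReadSimSpec:
    """Read simulator settings.

    Long mode emulates near-accurate circular-consensus long reads (the study
    conditions: mean 14.3 kb); short mode emulates 150 bp paired reads.  The
    error process applies substitutions and single-base indels in a fixed
    80/10/10 split of the per-base error rate.
    """

    mode: str = "long"                 # "long" | "short"
    mean_length: int = 14300
    length_sd: int = 3600
    min_length: int = 1000
    error_rate: float = 0.005
    depth: float | None = None         # mean fold-coverage over the community
    n_reads: int | None = None         # overrides depth when given
    insert_mean: int = 400             # short mode only
    insert_sd: int = 40
    rng_seed: int = 0

    @classmethod
    def short(cls, **kw) -> "ReadSimSpec":
        defaults = dict(mode="short", mean_length=150, length_sd=0, min_length=150,
                        error_rate=0.002)
        defaults.update(kw)
        return cls(**defaults)

    def validate(self) -> None:
        if self.mode not in ("long", "short"):
            raise ValueError(f"unknown read mode {self.mode!r}")
        if self.n_reads is None and (self.depth is None or self.depth <= 0):
            raise ValueError("depth must be positive (or give n_reads)")
        if self.n_reads is not None and self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate outside [0, 0.05]")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _signature_table(signature_seed: int) -> np.ndarray:
    """64x4 order-3 transition table sampled from the signature seed."""
    rng = np.random.default_rng(signature_seed)
    # moderate Dirichlet concentration: distinct signatures without
    # degenerate (near-deterministic) contexts
    return rng.dirichlet(np.full(4, 5.0), size=64)


def _stationary_gc(table: np.ndarray) -> tuple[np.ndarray, float]:
    """Stationary distribution over 64 contexts and implied stationary GC."""
    T = np.zeros((64, 64))
    for ctx in range(64):
        for b in range(4):
            nxt = (ctx * 4 + b) % 64
            T[ctx, nxt] += table[ctx, b]
    # power iteration: the chain is irreducible (all probs > 0)
    pi = np.full(64, 1.0 / 64)
    for _ in range(200):
        pi = pi @ T
    pi /= pi.sum()
    gc = float(pi @ (table @ _GC_MASK))
    return pi, gc


def _tilt_table(table: np.ndarray, gc_target: float) -> tuple[np.ndarray, np.ndarray]:
    """Exponentially tilt G/C emission so stationary GC hits gc_target."""

    def tilted(logt: float) -> np.ndarray:
        w = np.exp(logt * _GC_MASK)
        t = table * w
        return t / t.sum(axis=1, keepdims=True)

    def gap(logt: float) -> float:
        return _stationary_gc(tilted(logt))[1] - gc_target

    logt = brentq(gap, -8.0, 8.0, xtol=1e-10)
    t = tilted(logt)
    pi, _ = _stationary_gc(t)
    return t, pi


def generate_genome(spec: GenomeSpec, rng_seed: int = 0) -> SeqRecord:
    """Generate one genome; deterministic for a fixed (spec, seed).

    Realized GC lands within +/-0.01 of ``gc_target`` for lengths >= 50 kb.
    An embedded marker (if any) occurs exactly once; its position and strand
    are recorded in the record's ``meta``.
    """
    spec.validate()
    table, pi = _tilt_table(_signature_table(spec.signature_seed), spec.gc_target)
    cum = np.cumsum(table, axis=1)
    rng = np.random.default_rng([rng_seed, spec.signature_seed, 0x5e9])
    ctx = int(rng.choice(64, p=pi))
    u = rng.random(spec.length).tolist()
    cum_rows = cum.tolist()
    out = []
    append = out.append
    for ui in u:
        row = cum_rows[ctx]
        if ui < row[0]:
            b = 0
        elif ui < row[1]:
            b = 1
        elif ui < row[2]:
            b = 2
        else:
            b = 3
        append(BASES[b])
        ctx = (ctx * 4 + b) % 64
    seq = "".join(out)

    meta: dict = {}
    if spec.marker_template is not None:
        marker = mutate_sites(spec.marker_template, spec.marker_divergence, rng)
        mlen = len(marker)
        pos = int(rng.integers(0, spec.length - mlen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = marker if strand == "+" else reverse_complement(marker)
        seq = seq[:pos] + ins + seq[pos + mlen:]
        meta.update(marker_start=pos, marker_end=pos + mlen, marker_strand=strand,
                    marker_seq=marker)
    return SeqRecord(spec.name, seq, circular=spec.circular, meta=meta)


def mutate_sites(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute a Binomial(len, rate) set of sites; length is preserved."""
    if rate == 0.0:
        return seq
    n = int(rng.binomial(len(seq), rate))
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    arr = list(seq)
    for p in pos:
        choices = [b for b in BASES if b != arr[p]]
        arr[p] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def diversify_population(genome: SeqRecord, n_strains: int, divergence: float,
                         rng_seed: int = 0) -> list[SeqRecord]:
    """Independent per-strain substitution clouds around a parent genome."""
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if not 0.0 <= divergence <= 0.05:
        raise ValueError("divergence outside [0, 0.05]")
    rng = np.random.default_rng([rng_seed, 0x51f])
    strains = []
    for i in range(n_strains):
        seq = mutate_sites(genome.seq, divergence, rng)
        strains.append(SeqRecord(f"{genome.id}|s{i}", seq, circular=genome.circular,
                                 meta={"parent": genome.id, "strain": i}))
    return strains


# ---------------------------------------------------------------------------
# community assembly and read simulation
# ---------------------------------------------------------------------------

@dataclass
class Community:
    spec: CommunitySpec
    genomes: list[SeqRecord]                 # parent genome per member
    strains: list[list[SeqRecord]]           # strain sequences per member


def build_community(spec: CommunitySpec) -> Community:
    spec.validate()
    genomes, strains = [], []
    for i, m in enumerate(spec.members):
        g = generate_genome(m.genome, rng_seed=spec.rng_seed)
        genomes.append(g)
        if m.n_strains == 1 or m.population_divergence == 0.0:
            # divergence handling is a no-op for a single-strain population
            strs = diversify_population(g, m.n_strains, 0.0,
                                        rng_seed=spec.rng_seed + 7919 * i) \
                if m.n_strains > 1 else [dataclasses.replace(
                    g, id=f"{g.id}|s0", meta={**g.meta, "parent": g.id, "strain": 0})]
        else:
            strs = diversify_population(g, m.n_strains, m.population_divergence,
                                        rng_seed=spec.rng_seed + 7919 * i)
        strains.append(strs)
    return Community(spec, genomes, strains)


def log_skewed_abundances(n: int, sigma: float = 1.0, rng_seed: int = 0) -> list[float]:
    """Log-normal relative abundances, sorted descending and normalized."""
    rng = np.random.default_rng([rng_seed, 0xab])
    w = np.sort(rng.lognormal(0.0, sigma, size=n))[::-1]
    w /= w.sum()
    return [float(x) for x in w]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    u = rng.random(len(seq))
    hit = np.nonzero(u < rate)[0]
    if hit.size == 0:
        return seq
    kinds = rng.random(hit.size)
    out = []
    prev = 0
    for p, kind in zip(hit, kinds):
        out.append(seq[prev:p])
        base = seq[p]
        if kind < 0.8:  # substitution
            choices = [b for b in BASES if b != base]
            out.append(choices[int(rng.integers(0, 3))])
        elif kind < 0.9:  # single-base insertion before the site
            out.append(BASES[int(rng.integers(0, 4))] + base)
        # else: single-base deletion (emit nothing)
        prev = p + 1
    out.append(seq[prev:])
    return "".join(out)


def simulate_reads(community: Community | CommunitySpec,
                   readspec: ReadSimSpec) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw reads from a community; returns (reads, truth table).

    Read counts per member are multinomial in abundance x genome length.
    Long mode draws start positions uniformly (wrapping through the origin on
    circular genomes); short mode emits paired 150 bp ends of a fragment.
    The error process is applied after extraction.  Every read gets a truth
    row: source genome, strain index, 0-based half-open source interval (end
    may exceed L for origin-spanning reads, i.e. coordinates modulo L), strand.
    """
    if isinstance(community, CommunitySpec):
        community = build_community(community)
    readspec.validate()
    spec = community.spec
    rng = np.random.default_rng([readspec.rng_seed, spec.rng_seed, 0x6ead])

    lengths = np.array([len(g) for g in community.genomes], dtype=float)
    abund = np.array([m.abundance for m in spec.members])
    weights = abund * lengths
    weights /= weights.sum()

    if readspec.n_reads is not None:
        n_total = readspec.n_reads
    else:
        n_total = int(round(readspec.depth * lengths.sum() / readspec.mean_length))
    if readspec.mode == "short":
        n_total = max(1, n_total // 2)   # fragments; each yields two reads
    counts = rng.multinomial(n_total, weights)

    reads: list[SeqRecord] = []
    truth_rows: list[dict] = []
    ridx = 0

    for gi, (member, n_g) in enumerate(zip(spec.members, counts)):
        strains = community.strains[gi]
        genome_id = community.genomes[gi].id
        L = len(community.genomes[gi])
        circular = community.genomes[gi].circular
        for _ in range(int(n_g)):
            s_i = int(rng.integers(0, len(strains)))
            src = strains[s_i].seq
            if readspec.mode == "long":
                rl = int(rng.normal(readspec.mean_length, readspec.length_sd)) \
                    if readspec.length_sd > 0 else readspec.mean_length
                rl = max(readspec.min_length, rl)
                truncated = False
                if circular:
                    start = int(rng.integers(0, L))
                    rl = min(rl, L)  # a read never covers the circle twice
                    end = start + rl
                    frag = (src + src)[start:end]
                    wrapped = end > L
                else:
                    if rl > L:
                        rl, truncated = L, True
                    start = int(rng.integers(0, L - rl + 1))
                    end = start + rl
                    frag = src[start:end]
                    wrapped = False
                strand = "+" if rng.random() < 0.5 else "-"
                seq = frag if strand == "+" else reverse_complement(frag)
                seq = _apply_errors(seq, readspec.error_rate, rng)
                rid = f"read{ridx:07d}"
                reads.append(SeqRecord(rid, seq))
                truth_rows.append(dict(read_id=rid, genome=genome_id, strain=s_i,
                                       start=start, end=end, strand=strand,
                                       wrapped=wrapped, truncated=truncated))
                ridx += 1
            else:
                rl = readspec.mean_length
                ins = max(2 * rl, int(rng.normal(readspec.insert_mean, readspec.insert_sd))
                          if readspec.insert_sd > 0 else readspec.insert_mean)
                truncated = False
                if circular:
                    fstart = int(rng.integers(0, L))
                    ins = min(ins, L)
                    frag = (src + src)[fstart:fstart + ins]
                    wrapped = fstart + ins > L
                else:
                    if ins > L:
                        ins, truncated = L, True
                    fstart = int(rng.integers(0, L - ins + 1))
                    frag = src[fstart:fstart + ins]
                    wrapped = False
                rl = min(rl, ins)
                r1 = frag[:rl]
                r2 = reverse_complement(frag[-rl:])
                base = f"read{ridx:07d}"
                for mate, seq0, strand, s0, e0 in (
                        ("1", r1, "+", fstart, fstart + rl),
                        ("2", r2, "-", fstart + ins - rl, fstart + ins)):
                    seq = _apply_errors(seq0, readspec.error_rate, rng)
                    rid = f"{base}/{mate}"
                    reads.append(SeqRecord(rid, seq))
                    truth_rows.append(dict(read_id=rid, genome=genome_id, strain=s_i,
                                           start=s0, end=e0, strand=strand,
                                           wrapped=wrapped, truncated=truncated))
                ridx += 1

    truth = pd.DataFrame(truth_rows, columns=["read_id", "genome", "strain", "start",
                                              "end", "strand", "wrapped", "truncated"])
    return reads, truth


def fragment_genome(genome: SeqRecord, min_len: int = 5000, max_len: int = 50000,
                    rng_seed: int = 0) -> list[SeqRecord]:
    """Cut a genome into consecutive contigs with uniform random lengths —
    an assembly stand-in with known contig-to-genome truth."""
    rng = np.random.default_rng([rng_seed, 0xf2a6])
    contigs = []
    pos = 0
    i = 0
    while pos < len(genome):
        clen = int(rng.integers(min_len, max_len + 1))
        end = min(pos + clen, len(genome))
        if len(genome) - end < min_len:   # avoid a tiny trailing contig
            end = len(genome)
        contigs.append(SeqRecord(f"{genome.id}_c{i}", genome.seq[pos:end],
                                 meta={"genome": genome.id, "start": pos, "end": end}))
        pos = end
        i += 1
    return contigs


# ---------------------------------------------------------------------------
# auxiliary synthetic inputs (gene tables, marker references)
# ---------------------------------------------------------------------------

def simulate_gene_table(genome: SeqRecord, taxon: str | None,
                        mean_gene: int = 900, label_accuracy: float = 0.85,
                        unlabeled_fraction: float = 0.1,
                        wrong_labels: tuple[str, ...] = (),
                        rng_seed: int = 0) -> pd.DataFrame:
    """A gene table stand-in: tiled genes with best-hit taxonomy labels.

    Gene calling and homology annotation are inputs to the binning analysis,
    not part of it; this emulates their output with a configurable label
    accuracy and unlabeled fraction.
    """
    rng = np.random.default_rng([rng_seed, 0x9e2e])
    rows = []
    pos = int(rng.integers(0, 120))
    gi = 0
    while pos < len(genome) - 200:
        glen = int(np.clip(rng.normal(mean_gene, mean_gene / 4), 200, 3000))
        end = min(pos + glen, len(genome))
        u = rng.random()
        if taxon is None or u < unlabeled_fraction:
            label = None
        elif u < unlabeled_fraction + (1 - unlabeled_fraction) * label_accuracy or not wrong_labels:
            label = taxon
        else:
            label = wrong_labels[int(rng.integers(0, len(wrong_labels)))]
        rows.append(dict(contig_id=genome.id, gene_id=f"{genome.id}_g{gi}",
                         start=pos, end=end,
                         strand="+" if rng.random() < 0.5 else "-",
                         best_hit_taxon=label))
        pos = end + int(rng.integers(20, 200))
        gi += 1
    return pd.DataFrame(rows, columns=["contig_id", "gene_id", "start", "end",
                                       "strand", "best_hit_taxon"])


def make_marker_reference(taxa: list[str], length: int = 1500,
                          family_divergence: float = 0.10,
                          rng_seed: int = 0) -> list[SeqRecord]:
    """Synthetic 16S-like marker reference set, one sequence per taxon path.

    All members descend from one random ancestor at ``family_divergence``
    substitutions per site, so they are mutually alignable (like real rRNA)
    yet separable by identity.  Taxonomy is carried in the record metadata
    and written as semicolon-delimited header fields on export.
    """
    rng = np.random.default_rng([rng_seed, 0x165])
    ancestor = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    refs = []
    for i, taxon in enumerate(taxa):
        seq = mutate_sites(ancestor, family_divergence, rng)
        refs.append(SeqRecord(f"marker{i:03d}", seq,
                              meta={"taxonomy": taxon}))
    return refs


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_reads(reads: list[SeqRecord], path: str | Path, mode: str = "long") -> None:
    if mode == "long":
        write_fasta(reads, path)
    else:
        write_fastq(reads, path)


def write_manifest(spec: CommunitySpec, path: str | Path) -> None:
    doc = {
        "rng_seed": spec.rng_seed,
        "members": [
            {"name": m.genome.name, "length": m.genome.length,
             "gc_target": m.genome.gc_target, "signature_seed": m.genome.signature_seed,
             "circular": m.genome.circular, "abundance": m.abundance,
             "population_divergence": m.population_divergence,
             "n_strains": m.n_strains}
            for m in spec.members
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
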