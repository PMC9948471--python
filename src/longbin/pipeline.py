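"""Configuration-driven end-to-end runs.

A run simulates a community with ground truth, then walks the analysis the
package implements: composition profiles and metagenome ordination, gene
taxonomy consensus, contig binning with differential coverage, marker
detection and seeded read binning with redundancy removal and scaffolding,
fragment recruitment with presence calls and ANIr, and assembly QC.  Every
stage writes its tables under the output directory and can be re-run
individually (outputs of earlier stages are reloaded from disk), and a
resolved copy of the configuration plus a checksum manifest is written with
the results.  Identity/length thresholds default to the decision rules the
analysis is built around and are all configurable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from . import assembly_qc, binning, marker16s, recruitment, seqstats, simdata
from .records import SeqRecord, read_fasta, read_fastq, write_fasta

log = logging.getLogger("longbin.pipeline")

STAGES = ["simulate", "profile", "classify-contigs", "bin-contigs",
          "bin-reads", "recruit", "qc", "report"]

DEFAULT_MARKER_SET = [f"SCG{i:02d}" for i in range(43)]


@dataclass
class CommunityConfig:
    n_genomes: int = 5
    genome_length: int = 60000
    gc_min: float = 0.35
    gc_max: float = 0.65
    n_circular: int = 2
    diverse_member: int = 0          # index of the hyper-diverse population
    n_strains: int = 4
    population_divergence: float = 0.02
    abundance_sigma: float = 1.0     # log-skew of relative abundances
    marker_divergence: float = 0.05
    phyla: tuple = ("PhylumA", "PhylumB", "PhylumC")


@dataclass
class ReadsConfig:
    long_n: int = 600
    long_mean: int = 3000
    long_sd: int = 600
    long_error: float = 0.003
    short_metagenomes: int = 2
    short_fragments: int = 4000
    short_error: float = 0.002


@dataclass
class Thresholds:
    # fragment recruitment and presence calling
    recruit_identity: float = 95.0      # species-level read identity gate
    recruit_min_aln: int = 50
    genus_identity: float = 70.0        # genus-level sweep
    presence_min_rpkg: float = 3.0
    presence_min_breadth: float = 0.7
    anir_identity: float = 80.0
    anir_min_aln: int = 50
    # contig coverage
    coverage_identity: float = 99.0
    coverage_min_aln: int = 50
    coverage_subsample: int = 20_000_000
    # taxonomy consensus
    contig_min_len: int = 5000
    consensus_fraction: float = 0.5
    # read binning
    read_removal_identity: float = 97.0
    redundancy_identity: float = 99.0
    redundancy_short_cov: float = 0.9
    scaffold_identity: float = 99.0
    scaffold_min_overlap: int = 1000
    # markers
    marker_max_evalue: float = 1e-5
    classify_identity: float = 80.0
    classify_short_min_aln: int = 90
    classify_long_min_segment: int = 1000
    marker_derep_identity: float = 97.0
    display_floor: float = 0.01
    # QC
    qc_min_completeness: float = 40.0
    qc_max_contamination: float = 5.0
    circularity_identity: float = 95.0
    circularity_min_end: int = 250
    # dereplication and networks
    genome_derep_ani: float = 95.0
    aai_min_of: float = 0.25
    aai_min_aai: float = 30.0


@dataclass
class RunConfig:
    outdir: str = "longbin_run"
    rng_seed: int = 0
    community: CommunityConfig = field(default_factory=CommunityConfig)
    reads: ReadsConfig = field(default_factory=ReadsConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        t = self.thresholds
        for key in ("recruit_identity", "coverage_identity", "anir_identity",
                    "read_removal_identity", "redundancy_identity",
                    "scaffold_identity", "circularity_identity"):
            v = getattr(t, key)
            if not 0 < v <= 100:
                raise ValueError(f"threshold {key}={v} outside (0, 100]")
        for key in ("recruit_min_aln", "coverage_min_aln", "scaffold_min_overlap",
                    "circularity_min_end", "contig_min_len"):
            if getattr(t, key) <= 0:
                raise ValueError(f"threshold {key} must be positive")
        if self.community.n_genomes < 2:
            raise ValueError("need at least 2 genomes")


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    nested = {"community": CommunityConfig, "reads": ReadsConfig,
              "thresholds": Thresholds}
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in nested and isinstance(v, dict):
            v = _from_dict(nested[f.name], v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = _from_dict(RunConfig, data)
    cfg.validate()
    return cfg


def _dump_config(cfg: RunConfig, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _checksum_manifest(outdir: Path) -> None:
    rows = []
    for p in sorted(outdir.glob("*")):
        if p.name in ("checksums.tsv", "run.log") or p.is_dir():
            continue
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        rows.append(f"{h}\t{p.name}")
    (outdir / "checksums.tsv").write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _build_specs(cfg: RunConfig, marker_refs: list[SeqRecord]):
    c = cfg.community
    gcs = np.linspace(c.gc_min, c.gc_max, c.n_genomes)
    abund = simdata.log_skewed_abundances(c.n_genomes, c.abundance_sigma,
                                          rng_seed=cfg.rng_seed)
    members = []
    for i in range(c.n_genomes):
        gspec = simdata.GenomeSpec(
            name=f"G{i:02d}", length=c.genome_length, gc_target=float(gcs[i]),
            signature_seed=cfg.rng_seed * 1000 + i,
            circular=i < c.n_circular,
            marker_template=marker_refs[i % len(marker_refs)].seq,
            marker_divergence=c.marker_divergence)
        diverse = i == c.diverse_member
        members.append(simdata.CommunityMember(
            gspec, abund[i],
            population_divergence=c.population_divergence if diverse else 0.0,
            n_strains=c.n_strains if diverse else 1))
    return simdata.CommunitySpec(members, rng_seed=cfg.rng_seed)


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    c, r = cfg.community, cfg.reads
    taxa = [f"Bacteria;{c.phyla[i % len(c.phyla)]}" for i in range(c.n_genomes)]
    marker_refs = simdata.make_marker_reference(sorted(set(taxa)),
                                                rng_seed=cfg.rng_seed)
    cspec = _build_specs(cfg, marker_refs)
    community = simdata.build_community(cspec)
    write_fasta(community.genomes, outdir / "genomes.fasta")
    # marker (rRNA-like) intervals, masked out of later recruitment
    with open(outdir / "rrna_mask.bed", "w") as fh:
        for g in community.genomes:
            if "marker_start" in g.meta:
                fh.write(f"{g.id}\t{g.meta['marker_start']}\t{g.meta['marker_end']}\n")
    marker16s.write_marker_fasta(marker_refs, outdir / "marker_refs.fasta")
    simdata.write_manifest(cspec, outdir / "community.yaml")

    contigs = []
    for i, g in enumerate(community.genomes):
        contigs += simdata.fragment_genome(g, min_len=cfg.thresholds.contig_min_len,
                                           max_len=max(20000, c.genome_length // 4),
                                           rng_seed=cfg.rng_seed + i)
    write_fasta(contigs, outdir / "contigs.fasta")

    phyla_by_genome = {f"G{i:02d}": c.phyla[i % len(c.phyla)]
                       for i in range(c.n_genomes)}
    tables = []
    rng = np.random.default_rng([cfg.rng_seed, 0x3e7e])
    for ci, contig in enumerate(contigs):
        tab = simdata.simulate_gene_table(
            contig, phyla_by_genome[contig.meta["genome"]],
            wrong_labels=tuple(c.phyla), rng_seed=cfg.rng_seed + 31 * ci)
        tables.append(tab)
    genes = pd.concat(tables, ignore_index=True)
    # sprinkle single-copy marker annotations: one gene per marker per genome
    genes["marker"] = ""
    for gname in sorted(phyla_by_genome):
        rows = genes.index[genes.contig_id.str.startswith(gname + "_")]
        chosen = rng.choice(rows, size=min(len(DEFAULT_MARKER_SET), len(rows)),
                            replace=False)
        for m, idx in zip(DEFAULT_MARKER_SET, chosen):
            genes.loc[idx, "marker"] = m
    _write_tsv(genes, outdir / "genes.tsv")

    long_spec = simdata.ReadSimSpec(mode="long", mean_length=r.long_mean,
                                    length_sd=r.long_sd, min_length=500,
                                    error_rate=r.long_error, n_reads=r.long_n,
                                    rng_seed=cfg.rng_seed)
    long_reads, long_truth = simdata.simulate_reads(community, long_spec)
    simdata.write_reads(long_reads, outdir / "reads_long.fasta", "long")
    simdata.write_truth(long_truth, outdir / "truth_long.tsv")

    rng2 = np.random.default_rng([cfg.rng_seed, 0x51a0])
    for m in range(r.short_metagenomes):
        perm = rng2.permutation(c.n_genomes)
        members = [dataclasses.replace(cfg_m, abundance=cspec.members[perm[i]].abundance)
                   for i, cfg_m in enumerate(cspec.members)]
        mspec = simdata.CommunitySpec(members, rng_seed=cspec.rng_seed)
        reads, truth = simdata.simulate_reads(
            simdata.Community(mspec, community.genomes, community.strains),
            simdata.ReadSimSpec.short(n_reads=2 * r.short_fragments,
                                      error_rate=r.short_error,
                                      rng_seed=cfg.rng_seed + 101 + m))
        simdata.write_reads(reads, outdir / f"metagenome_M{m}.fastq", "short")
        simdata.write_truth(truth, outdir / f"truth_M{m}.tsv")


def _load_short_metagenomes(cfg: RunConfig, outdir: Path) -> dict[str, list[SeqRecord]]:
    out = {}
    for m in range(cfg.reads.short_metagenomes):
        out[f"M{m}"] = read_fastq(outdir / f"metagenome_M{m}.fastq")
    return out


def stage_profile(cfg: RunConfig, outdir: Path) -> None:
    contigs = read_fasta(outdir / "contigs.fasta")
    profs = [seqstats.composition_profile(c, k=4) for c in contigs]
    mat = np.vstack([p.kmer_freq for p in profs])
    ord_res = seqstats.pca(mat, n_components=3)
    df = pd.DataFrame(ord_res.coordinates, columns=["PC1", "PC2", "PC3"])
    df.insert(0, "contig_id", [p.seq_id for p in profs])
    df["gc"] = [p.gc for p in profs]
    df["length"] = [p.length for p in profs]
    _write_tsv(df, outdir / "contig_profiles.tsv")

    # whole-metagenome comparison: Bray-Curtis on pooled read k-mer profiles
    sets = _load_short_metagenomes(cfg, outdir)
    sets["PB_long"] = read_fasta(outdir / "reads_long.fasta")
    names = sorted(sets)
    profiles = [seqstats.metagenome_kmer_profile(sets[n], k=4) for n in names]
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = seqstats.bray_curtis(profiles[i], profiles[j])
    pco = seqstats.pcoa(D, ids=names)
    cols = [f"Axis{i+1}" for i in range(pco.coordinates.shape[1])]
    df2 = pd.DataFrame(pco.coordinates, columns=cols)
    df2.insert(0, "metagenome", names)
    _write_tsv(df2, outdir / "metagenome_ordination.tsv")


def stage_classify_contigs(cfg: RunConfig, outdir: Path) -> None:
    contigs = read_fasta(outdir / "contigs.fasta")
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    tax = binning.classify_contigs(contigs, genes,
                                   min_len=cfg.thresholds.contig_min_len,
                                   min_fraction=cfg.thresholds.consensus_fraction)
    df = pd.DataFrame(sorted(tax.items()), columns=["contig_id", "taxon"])
    _write_tsv(df, outdir / "taxonomy.tsv")


def stage_bin_contigs(cfg: RunConfig, outdir: Path) -> None:
    t = cfg.thresholds
    contigs = read_fasta(outdir / "contigs.fasta")
    metagenomes = _load_short_metagenomes(cfg, outdir)
    cov = binning.contig_coverage(contigs, metagenomes,
                                  min_identity=t.coverage_identity,
                                  min_aln=t.coverage_min_aln,
                                  subsample=t.coverage_subsample)
    _write_tsv(cov.rename_axis("contig_id"), outdir / "coverage.tsv", index=True)
    tax = dict(pd.read_csv(outdir / "taxonomy.tsv", sep="\t").values)
    ba = binning.bin_contigs(contigs, cov, tax)
    df = pd.DataFrame(sorted(ba.assignments.items()), columns=["contig_id", "bin"])
    _write_tsv(df, outdir / "bins_contigs.tsv")
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    summary = binning.summarize_bins(ba, contigs, genes)
    # per-bin RPKG per metagenome (bin treated as one genome)
    for mg in cov.columns:
        vals = []
        for lab in summary.index:
            members = ba.members_of(lab)
            sub = cov.loc[members]
            lens = np.array([len(c) for c in contigs if c.id in set(members)])
            vals.append(float(np.average(sub[mg], weights=lens)) if len(lens) else 0.0)
        summary[f"rpkg_{mg}"] = vals
    _write_tsv(summary.rename_axis("bin"), outdir / "bin_summary.tsv", index=True)


def stage_bin_reads(cfg: RunConfig, outdir: Path) -> None:
    t = cfg.thresholds
    reads = read_fasta(outdir / "reads_long.fasta")
    marker_refs = marker16s.read_marker_fasta(outdir / "marker_refs.fasta")
    hits = marker16s.find_marker_candidates(reads, marker_refs,
                                            max_evalue=t.marker_max_evalue)
    valid = [h for h in hits if marker16s.validate_marker(h, marker_refs)]
    for h in valid:
        h.taxon_path = marker16s.classify_marker(
            h, marker_refs, "long", min_identity=t.classify_identity,
            long_min_segment=t.classify_long_min_segment)
    _write_tsv(marker16s.hits_to_table(valid), outdir / "markers_long.tsv")

    profile = marker16s.taxon_profile(
        [h.taxon_path for h in valid], level=1,
        min_display_fraction=t.display_floor)
    prof_df = pd.DataFrame(sorted(profile.fractions.items()),
                           columns=["taxon", "fraction"])
    prof_df["display"] = [tx if tx in profile.display else "other"
                          for tx in prof_df.taxon]
    _write_tsv(prof_df, outdir / "taxon_profile.tsv")

    # target the hyper-diverse population's phylum for seeded binning
    seeds = [h.source_id for h in valid
             if len(h.segment) >= t.classify_long_min_segment]
    if not seeds:
        raise RuntimeError("no validated marker-bearing seed reads found")
    ba = binning.seeded_read_binning(
        reads, seeds, known_genomes=None,
        remove_identity=t.read_removal_identity,
        seed_markers={h.source_id: h.best_ref for h in valid})
    df = pd.DataFrame(sorted(ba.assignments.items()), columns=["read_id", "bin"])
    _write_tsv(df, outdir / "read_bins.tsv")

    by_id = {r.id: r for r in reads}
    scaffolds = []
    for lab in ba.labels:
        members = [by_id[m] for m in ba.members_of(lab)]
        nr, _ = binning.remove_redundancy(members, identity=t.redundancy_identity,
                                          short_cov=t.redundancy_short_cov)
        merged = binning.scaffold_bin(nr, min_identity=t.scaffold_identity,
                                      min_overlap=t.scaffold_min_overlap)
        for i, frag in enumerate(merged):
            scaffolds.append(SeqRecord(f"{lab}_frag{i:03d}", frag.seq))
    write_fasta(scaffolds, outdir / "scaffolds.fasta")


def stage_recruit(cfg: RunConfig, outdir: Path) -> None:
    t = cfg.thresholds
    genomes = read_fasta(outdir / "genomes.fasta")
    metagenomes = _load_short_metagenomes(cfg, outdir)
    metagenomes["PB_long"] = read_fasta(outdir / "reads_long.fasta")
    mask_path = outdir / "rrna_mask.bed"
    masks = recruitment.read_bed_mask(mask_path) if mask_path.exists() else {}
    mat = recruitment.recruitment_matrix(
        genomes, metagenomes,
        identity_levels=(t.recruit_identity, t.genus_identity),
        min_aln=t.recruit_min_aln, rrna_masks=masks)
    _write_tsv(mat, outdir / "recruitment.tsv")


def stage_qc(cfg: RunConfig, outdir: Path) -> None:
    t = cfg.thresholds
    genomes = read_fasta(outdir / "genomes.fasta")
    rng = np.random.default_rng([cfg.rng_seed, 0x0c])
    rows = []
    for g in genomes:
        if g.circular:
            rot = int(rng.integers(1000, len(g) - 1000))
            lag = SeqRecord(g.id, g.seq[rot:] + g.seq[:rot])
            junction = SeqRecord(f"{g.id}_junction",
                                 g.seq[max(0, rot - 1500):rot + 1500])
            others = [SeqRecord(f"{g.id}_int", g.seq[2000:5000]), junction]
        else:
            lag = g
            others = [SeqRecord(f"{g.id}_int", g.seq[2000:5000])]
        ev = assembly_qc.check_circular(lag, others,
                                       min_identity=t.circularity_identity,
                                       min_end_aln=t.circularity_min_end)
        rows.append(ev)
    _write_tsv(assembly_qc.evidence_table(rows), outdir / "qc_circularity.tsv")

    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    genes["genome"] = genes.contig_id.str.replace(r"_c\d+$", "", regex=True)
    results = []
    for gname, sub in genes.groupby("genome"):
        labels = [m for m in sub.marker if isinstance(m, str) and m]
        results.append(assembly_qc.marker_completeness(labels, DEFAULT_MARKER_SET,
                                                       genome_id=gname))
    kept = assembly_qc.filter_genomes(results, t.qc_min_completeness,
                                      t.qc_max_contamination)
    df = pd.DataFrame([dict(genome=r.genome_id,
                            completeness=round(r.completeness, 1),
                            contamination=round(r.contamination, 1),
                            kept=r.genome_id in kept) for r in results])
    _write_tsv(df, outdir / "qc_markers.tsv")


def stage_report(cfg: RunConfig, outdir: Path) -> None:
    t = cfg.thresholds
    # AAI network over the hyper-diverse population (parent + strains),
    # peptides translated from the parent's gene calls
    genomes = read_fasta(outdir / "genomes.fasta")
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    diverse = genomes[cfg.community.diverse_member]
    strains = simdata.diversify_population(
        diverse, cfg.community.n_strains, cfg.community.population_divergence,
        rng_seed=cfg.rng_seed + 7919 * cfg.community.diverse_member)
    proteomes = {}
    sub = genes[genes.contig_id.str.startswith(diverse.id + "_")].head(40)
    contig_offsets = {}
    contigs = read_fasta(outdir / "contigs.fasta")
    for c in contigs:
        if c.id.startswith(diverse.id + "_"):
            contig_offsets[c.id] = c
    for member in [diverse] + strains[:2]:
        peps = []
        for row in sub.itertuples():
            contig = contig_offsets[row.contig_id]
            gstart = contig.meta.get("start", 0) if contig.meta else 0
            s, e = row.start, row.end
            dna = member.seq[gstart + s: gstart + e]
            dna = dna[: 3 * (len(dna) // 3)]
            if len(dna) >= 60:
                peps.append(SeqRecord(f"{member.id}|{row.gene_id}",
                                      str(Seq(dna).translate()).replace("*", "X")))
        proteomes[member.id] = peps
    edges = recruitment.aai_network(proteomes, min_of=t.aai_min_of,
                                    min_aai=t.aai_min_aai)
    _write_tsv(recruitment.network_to_table(edges), outdir / "aai_network.tsv")

    report = {"sections": {}}
    for name, fname in [("bin_summary", "bin_summary.tsv"),
                        ("recruitment", "recruitment.tsv"),
                        ("taxon_profile", "taxon_profile.tsv"),
                        ("aai_network", "aai_network.tsv"),
                        ("circularity", "qc_circularity.tsv")]:
        path = outdir / fname
        if not path.exists():
            raise RuntimeError(f"report input missing: {fname}")
        df = pd.read_csv(path, sep="\t")
        report["sections"][name] = {"rows": int(len(df)),
                                    "columns": list(df.columns)}
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "profile": stage_profile,
    "classify-contigs": stage_classify_contigs,
    "bin-contigs": stage_bin_contigs,
    "bin-reads": stage_bin_reads,
    "recruit": stage_recruit,
    "qc": stage_qc,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (all by default) in dependency order."""
    cfg.validate()
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        _dump_config(cfg, outdir / "config_resolved.yaml")
        for name in STAGES:
            if name not in stages:
                continue
            log.info("stage %s: start", name)
            try:
                _STAGE_FUNCS[name](cfg, outdir)
            except Exception as exc:
                log.error("stage %s: failed: %s", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
        _checksum_manifest(outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
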