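"""Shared run configuration for the numbered analysis scripts.

All scripts operate on one run directory (default ``results/demo``) so that
each stage can pick up the previous stage's outputs; pass ``--outdir`` and
``--seed`` to change the run.
"""

import argparse

from longbin.pipeline import CommunityConfig, ReadsConfig, RunConfig


def parse_args(description: str) -> argparse.Namespace:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--outdir", default="results/demo")
    p.add_argument("--seed", type=int, default=1)
    return p.parse_args()


def demo_config(outdir: str, seed: int) -> RunConfig:
    """The demo community: five genomes spanning GC 35-65%, two circular
    replicons, one hyper-diverse population (4 strains at 2% divergence),
    log-skewed abundances, one long-read set and two short-read metagenomes
    with shuffled abundance profiles."""
    return RunConfig(
        outdir=outdir, rng_seed=seed,
        community=CommunityConfig(n_genomes=5, genome_length=60000,
                                  n_circular=2),
        reads=ReadsConfig(long_n=600, short_metagenomes=2,
                          short_fragments=4000))
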