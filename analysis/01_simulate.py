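#!/usr/bin/env python
"""Simulate the synthetic aviary study population and write its fixtures.

Generates a population shaped like the aviary breeding study (14 aviaries,
4-5 pairs each, ~290 embryos from ~60 families), the engineered MHC allele
pool (85 DNA -> 78 AA -> 59 functional alleles, 10 common), microsatellite
genotypes, and two runs of noisy tagged amplicon reads with technical
replicates.  Everything downstream (02-05) reads from results/fixtures.
"""

import sys
from pathlib import Path

from sparrowmhc.simulate import (
    SimConfig,
    simulate_population,
    simulate_reads,
    write_fixtures,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/fixtures")


def main() -> None:
    cfg = SimConfig(seed=SEED)
    pop = simulate_population(cfg)
    matrices, tag_map = simulate_reads(pop, cfg)
    write_fixtures(pop, OUT, matrices=matrices, tag_map=tag_map)

    off = pop.individuals[pop.individuals["role"] == "offspring"]
    print(f"seed {SEED}: {len(off)} offspring from {len(pop.pairs)} pairs "
          f"in {pop.individuals['aviary'].nunique()} aviaries")
    print(f"allele pool: {len(pop.pool.sequences)} DNA alleles, "
          f"{len(pop.pool.fa_ids)} functional alleles "
          f"({len(pop.pool.common_fas)} designed common)")
    for mat in matrices:
        print(f"run {mat.run_id}: {len(mat.counts)} samples, "
              f"{mat.total_reads} reads, {len(mat.replicate_links)} replicates")
    print(f"fixtures -> {OUT}")


if __name__ == "__main__":
    main()
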