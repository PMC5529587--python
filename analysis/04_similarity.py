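#!/usr/bin/env python
"""Parental MHC similarity and offspring microsatellite heterozygosity.

For every breeding pair: the proportion of functional alleles shared
(100/(n_male + n_female) x n_shared), the unweighted UniFrac distance of
the parents' allele sets on the allele tree, and the same on the
functional-allele (z-descriptor) tree.  Also computes per-individual
multilocus heterozygosity over the 10 neutral microsatellite loci.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from sparrowmhc.similarity import (
    UniFracTree,
    heterozygosity_from_table,
    pair_similarities,
)

FIX = Path("results/fixtures")
OUT = Path("results")


def main() -> None:
    pairs = pd.read_csv(FIX / "pairs.tsv", sep="\t")
    geno = pd.read_csv(OUT / "genotypes.tsv", sep="\t")
    geno = geno[geno["allele"] != "novel"]
    alleles, fa_names = {}, {}
    for rec in SeqIO.parse(str(FIX / "alleles.fasta"), "fasta"):
        alleles[rec.id] = str(rec.seq)
        for field in rec.description.split():
            if field.startswith("fa="):
                fa_names[rec.id] = field[3:]

    allele_sets = {i: set(s["allele"]) for i, s in geno.groupby("individual")}
    fa_sets = {i: {fa_names[a] for a in s} for i, s in allele_sets.items()}

    callable_pairs = pairs[
        pairs["male"].map(lambda m: bool(fa_sets.get(m)))
        & pairs["female"].map(lambda f: bool(fa_sets.get(f)))]
    dropped = len(pairs) - len(callable_pairs)

    allele_tree = UniFracTree.from_newick(str(FIX / "allele_tree.nwk"))
    fa_tree = UniFracTree.from_newick(str(FIX / "fa_tree.nwk"))
    sim = pair_similarities(callable_pairs, allele_sets, fa_sets,
                            allele_tree, fa_tree)
    sim.to_csv(OUT / "pair_similarity.tsv", sep="\t", index=False)

    msat = pd.read_csv(FIX / "microsatellites.tsv", sep="\t")
    het = heterozygosity_from_table(msat)
    het.rename_axis("individual").to_csv(OUT / "heterozygosity.tsv", sep="\t")

    print(f"{len(sim)} pairs scored ({dropped} dropped for missing genotypes)")
    print(sim[["proportion_shared", "allele_distance", "fa_distance"]]
          .describe().loc[["mean", "std", "min", "max"]].round(3))
    print(f"heterozygosity: mean {het.mean():.3f} over {len(het)} individuals")
    print("-> results/pair_similarity.tsv, results/heterozygosity.tsv")


if __name__ == "__main__":
    main()
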