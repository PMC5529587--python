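#!/usr/bin/env python
"""Collapse called DNA alleles into functional alleles and tabulate
carrier frequencies.

Translation -> identical-AA grouping -> extraction of the 16 PBR residues
-> z-descriptor coding -> functional-allele classes.  Writes the FA table,
the offspring presence/absence matrix and carrier frequencies, and reports
the collapse counts and the common (>10%) allele list.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from sparrowmhc.functional import FunctionalMap, fa_presence_and_frequency

FIX = Path("results/fixtures")
OUT = Path("results")


def main() -> None:
    alleles, fa_names = {}, {}
    for rec in SeqIO.parse(str(FIX / "alleles.fasta"), "fasta"):
        alleles[rec.id] = str(rec.seq)
        for field in rec.description.split():
            if field.startswith("fa="):       # generator's FA label
                fa_names[rec.id] = field[3:]
    fmap = FunctionalMap.build(alleles)
    # display collapse classes under the generator's FA labels where known
    for fa in fmap.fas:
        dna_members = [m for a in fa.members
                       for m in next(x for x in fmap.aa_alleles
                                     if x.id == a).members]
        if dna_members and dna_members[0] in fa_names:
            fa.id = fa_names[dna_members[0]]
    fmap.aa_to_fa = {m: f.id for f in fmap.fas for m in f.members}
    n_dna, n_aa, n_fa = fmap.counts()
    print(f"collapse: {n_dna} DNA alleles -> {n_aa} AA alleles -> {n_fa} FAs")

    geno = pd.read_csv(OUT / "genotypes.tsv", sep="\t")
    geno = geno[geno["allele"] != "novel"]
    pheno = pd.read_csv(FIX / "pedigree_phenotypes.tsv", sep="\t")
    offspring = set(pheno.loc[pheno["role"] == "offspring", "individual"])
    sets = {i: set(s["allele"]) for i, s in geno.groupby("individual")
            if i in offspring}
    fa_of = {d: fmap.fa_of_dna(d) for d in alleles}
    presence, freqs, common = fa_presence_and_frequency(sets, fa_of, cutoff=0.10)

    rows = [{"fa_id": f.id, "pbr": f.pbr, "n_members": len(f.members),
             "frequency": float(freqs.get(f.id, 0.0))} for f in fmap.fas]
    pd.DataFrame(rows).sort_values("frequency", ascending=False).to_csv(
        OUT / "fa_table.tsv", sep="\t", index=False)
    presence.rename_axis("individual").to_csv(OUT / "fa_presence.tsv", sep="\t")

    print(f"{len(sets)} genotyped offspring; {len(common)} FAs above 10%:")
    for fa in common:
        print(f"  {fa}: {freqs[fa]:.2%}")
    print("-> results/fa_table.tsv, results/fa_presence.tsv")


if __name__ == "__main__":
    main()
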