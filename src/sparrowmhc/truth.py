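"""Analysis inputs computed from a simulated population's true genotypes.

Bypasses read simulation and genotype calling: presence/absence, carrier
frequencies, heterozygosity and parental similarity are derived directly
from the generator's true allele sets.  Used to study the statistical
machinery (power, calibration) separately from genotyping noise.
"""

from __future__ import annotations

import pandas as pd

from .similarity import UniFracTree, heterozygosity_from_table, pair_similarities
from .simulate import TruePopulation, fixture_trees
from .tables import build_analysis_table


def true_fa_presence(pop: TruePopulation,
                     cutoff: float = 0.10) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """FA presence/absence and carrier frequencies over offspring."""
    off = pop.individuals.loc[pop.individuals["role"] == "offspring", "individual"]
    inds = sorted(off)
    fas = sorted({fa for i in inds for fa in pop.fa_sets[i]})
    presence = pd.DataFrame(0, index=inds, columns=fas, dtype=int)
    for i in inds:
        for fa in pop.fa_sets[i]:
            presence.loc[i, fa] = 1
    freq = presence.mean(axis=0)
    common = sorted(freq.index[freq > cutoff])
    return presence, freq, common


def true_pair_similarity(pop: TruePopulation,
                         with_trees: bool = True) -> pd.DataFrame:
    """Similarity records from true parental allele/FA sets."""
    if with_trees:
        allele_nwk, fa_nwk = fixture_trees(pop.pool)
        atree = UniFracTree.from_newick(allele_nwk, is_path=False)
        ftree = UniFracTree.from_newick(fa_nwk, is_path=False)
        return pair_similarities(pop.pairs, pop.allele_sets, pop.fa_sets,
                                 atree, ftree)
    from .similarity import proportion_shared
    rows = [{"pair": r["pair_id"],
             "proportion_shared": proportion_shared(pop.fa_sets[r["male"]],
                                                    pop.fa_sets[r["female"]]),
             "allele_distance": 0.0, "fa_distance": 0.0}
            for _, r in pop.pairs.iterrows()]
    return pd.DataFrame(rows)


def true_analysis_table(pop: TruePopulation, response: str,
                        cutoff: float = 0.10,
                        with_trees: bool = True,
                        common: list[str] | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Per-response analysis table straight from the simulation truth.

    ``common`` fixes the FA predictor list (e.g. the generator's designed
    common alleles); by default the realized >cutoff alleles are used.
    """
    presence, _, realized_common = true_fa_presence(pop, cutoff=cutoff)
    if common is None:
        common = realized_common
    else:
        common = [fa for fa in common if fa in presence.columns]
    het = heterozygosity_from_table(pop.microsats)
    sim_tab = true_pair_similarity(pop, with_trees=with_trees)
    pheno = pop.individuals[pop.individuals["role"] == "offspring"].reset_index(drop=True)
    return build_analysis_table(pheno, presence, het, common,
                                pair_similarity=sim_tab, response=response)
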