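"""Parental MHC similarity and neutral heterozygosity.

Three MHC similarity measures between the members of a breeding pair:

* proportion of functional alleles shared,
  100 / (n alleles male + n alleles female) * n shared (sets, shared
  counted once, so identical parents score 50);
* unweighted UniFrac distance between the parents' allele sets on a rooted
  allele tree;
* the same on a functional-allele (z-descriptor) tree.

Plus multilocus heterozygosity over 10 neutral microsatellite loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import pandas as pd


def proportion_shared(set_a: set, set_b: set, count_both: bool = False) -> float:
    """Percentage of functional alleles shared between two parents.

    100 / (|A| + |B|) * |A intersect B|; with ``count_both`` the shared
    alleles are counted once per parent (doubling the score).
    """
    if not set_a or not set_b:
        raise ValueError("both allele sets must be non-empty")
    shared = len(set(set_a) & set(set_b))
    if count_both:
        shared *= 2
    return 100.0 / (len(set(set_a)) + len(set(set_b))) * shared


class UniFracTree:
    """A rooted tree with branch lengths, prepared for unweighted UniFrac."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._leaf_sets: list[tuple[frozenset, float]] = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue  # the root has no subtending branch
            length = node.edge.length or 0.0
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            self._leaf_sets.append((leaves, float(length)))
        self.leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}

    @classmethod
    def from_newick(cls, source: str, is_path: bool = True) -> "UniFracTree":
        kwargs = {"path" if is_path else "data": str(source)}
        tree = dendropy.Tree.get(schema="newick", preserve_underscores=True,
                                 **kwargs)
        return cls(tree)

    def unifrac(self, set_a, set_b) -> float:
        """Unweighted UniFrac between two leaf-id sets.

        (branch length subtending only A-leaves + only B-leaves) /
        (branch length subtending any leaf of A union B).  Zero-length
        branches contribute to neither sum; multifurcations are fine.
        """
        a, b = set(set_a), set(set_b)
        missing = (a | b) - self.leaf_labels
        if missing:
            raise KeyError(f"ids not present as tree leaves: {sorted(missing)}")
        unique = observed = 0.0
        for leaves, length in self._leaf_sets:
            in_a = not leaves.isdisjoint(a)
            in_b = not leaves.isdisjoint(b)
            if in_a or in_b:
                observed += length
                if in_a != in_b:
                    unique += length
        if observed == 0.0:
            return 0.0
        return unique / observed


def unifrac_distance(tree: UniFracTree, set_a, set_b) -> float:
    return tree.unifrac(set_a, set_b)


@dataclass
class SimilarityRecord:
    pair: str
    proportion_shared: float
    allele_distance: float
    fa_distance: float


def pair_similarities(pairs: pd.DataFrame,
                      allele_sets: dict[str, set[str]],
                      fa_sets: dict[str, set[str]],
                      allele_tree: UniFracTree,
                      fa_tree: UniFracTree,
                      count_both: bool = False) -> pd.DataFrame:
    """One similarity record per breeding pair.

    ``pairs`` needs columns pair_id, male, female.  Allele/FA coverage of
    the trees is validated for every pair before any record is emitted.
    """
    for _, row in pairs.iterrows():
        for parent in (row["male"], row["female"]):
            missing_a = allele_sets[parent] - allele_tree.leaf_labels
            missing_f = fa_sets[parent] - fa_tree.leaf_labels
            if missing_a or missing_f:
                raise KeyError(
                    f"tree coverage gap for {parent}: "
                    f"alleles {sorted(missing_a)}, FAs {sorted(missing_f)}")
    records = []
    for _, row in pairs.iterrows():
        m, f = row["male"], row["female"]
        records.append(SimilarityRecord(
            pair=row["pair_id"],
            proportion_shared=proportion_shared(fa_sets[m], fa_sets[f],
                                                count_both=count_both),
            allele_distance=allele_tree.unifrac(allele_sets[m], allele_sets[f]),
            fa_distance=fa_tree.unifrac(fa_sets[m], fa_sets[f]),
        ))
    return pd.DataFrame([vars(r) for r in records])


def multilocus_heterozygosity(genotype: dict[str, tuple | None]) -> float:
    """Proportion of typed microsatellite loci that are heterozygous.

    Loci with missing genotypes are excluded from numerator and
    denominator; at least one typed locus is required.
    """
    typed = [g for g in genotype.values() if g is not None]
    if not typed:
        raise ValueError("no typed loci")
    het = sum(1 for a, b in typed if a != b)
    return het / len(typed)


def heterozygosity_from_table(table: pd.DataFrame) -> pd.Series:
    """Per-individual heterozygosity from a long microsatellite table.

    Columns: individual, locus, a1, a2; blank/NaN allele sizes mark a
    missing locus.
    """
    out = {}
    for ind, sub in table.groupby("individual"):
        geno = {}
        for _, row in sub.iterrows():
            a1, a2 = row["a1"], row["a2"]
            if pd.isna(a1) or pd.isna(a2) or a1 == "" or a2 == "":
                geno[row["locus"]] = None
            else:
                geno[row["locus"]] = (int(a1), int(a2))
        out[ind] = multilocus_heterozygosity(geno)
    return pd.Series(out, name="heterozygosity")
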