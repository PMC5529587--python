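"""Functional MHC alleles: translation, PBR extraction and z-scale coding.

DNA alleles that translate to the same amino-acid sequence are synonymous;
amino-acid alleles whose 16 peptide-binding-region (PBR) residues are
identical present the same antigen repertoire and are collapsed into one
*functional allele* (FA).  PBR residues are encoded with the five published
physicochemical z-descriptors (z1 hydrophobicity, z2 steric bulk, z3
polarity, z4/z5 electronic effects), giving each FA a 16 x 5 matrix used
for functional distance trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Seq import Seq


class TranslationError(ValueError):
    pass


def load_zscales(path=None) -> pd.DataFrame:
    """z-descriptor table: index amino acid, columns z1..z5."""
    if path is None:
        path = resources.files("sparrowmhc.data") / "zscales.tsv"
    tab = pd.read_csv(path, sep="\t", comment="#", index_col="aa")
    if sorted(tab.index) != sorted("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError("z-scale table must cover exactly the 20 standard residues")
    return tab


def load_pbr_positions(path=None) -> list[int]:
    """Ordered 1-based codon indices of the PBR on the 222-bp frame."""
    if path is None:
        path = resources.files("sparrowmhc.data") / "pbr_positions.txt"
    with open(path) as fh:
        positions = [int(line.split()[0]) for line in fh
                     if line.strip() and not line.startswith("#")]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise ValueError("PBR positions must be strictly increasing")
    return positions


def translate_allele(dna: str) -> str:
    """Translate an exon-3 allele in frame 0 under the standard code.

    Rejects sequences whose length is not a whole number of codons, that
    contain ambiguous bases, or that translate with an internal stop.
    """
    dna = dna.upper()
    bad = set(dna) - set("ACGT")
    if bad:
        pos = next(i for i, c in enumerate(dna) if c in bad)
        raise TranslationError(f"ambiguous base {dna[pos]!r} at position {pos + 1}")
    if len(dna) % 3 != 0:
        raise TranslationError(f"length {len(dna)} is not a multiple of 3")
    aa = str(Seq(dna).translate())
    if "*" in aa:
        raise TranslationError(f"internal stop codon at residue {aa.index('*') + 1}")
    return aa


@dataclass
class AminoAcidAllele:
    id: str
    aa: str
    members: list[str]            # DNA allele ids sharing this translation


@dataclass
class FunctionalAllele:
    id: str
    pbr: str                      # 16-residue PBR string
    members: list[str]            # member AA allele ids
    z_matrix: np.ndarray | None = None
    frequency: float = float("nan")


def collapse_aa(dna_alleles: dict[str, str]) -> list[AminoAcidAllele]:
    """Group DNA alleles (id -> sequence) by identical translation."""
    groups: dict[str, list[str]] = {}
    for aid in sorted(dna_alleles):
        aa = translate_allele(dna_alleles[aid])
        groups.setdefault(aa, []).append(aid)
    out = []
    for i, aa in enumerate(sorted(groups), start=1):
        out.append(AminoAcidAllele(id=f"AA{i:03d}", aa=aa, members=groups[aa]))
    return out


def extract_pbr(aa: str, positions: list[int], reference_len: int | None = None) -> str:
    """Concatenate the residues at the 1-based PBR ``positions``.

    Sequences one codon longer than the reference frame (225-bp alleles on
    a 222-bp reference) are handled by codon-preserving anchoring: the
    extra residue is assumed inserted at the C-terminal end beyond the last
    PBR position, so positions apply unchanged.  Longer mismatches raise.
    """
    if reference_len is not None and len(aa) not in (reference_len, reference_len + 1):
        raise ValueError(f"sequence length {len(aa)} incompatible with "
                         f"reference length {reference_len}")
    if positions[-1] > len(aa):
        raise ValueError(f"PBR position {positions[-1]} beyond sequence "
                         f"length {len(aa)}")
    if min(positions) < 1:
        raise ValueError("PBR positions are 1-based")
    return "".join(aa[p - 1] for p in positions)


def encode_z(pbr: str, table: pd.DataFrame | None = None) -> np.ndarray:
    """16 x 5 matrix of z-descriptors, one row per PBR residue."""
    if table is None:
        table = load_zscales()
    missing = set(pbr) - set(table.index)
    if missing:
        raise ValueError(f"non-standard residues in PBR string: {sorted(missing)}")
    return table.loc[list(pbr)].to_numpy(dtype=float)


def collapse_functional(aa_alleles: list[AminoAcidAllele],
                        positions: list[int] | None = None,
                        ztable: pd.DataFrame | None = None) -> list[FunctionalAllele]:
    """Group AA alleles with identical PBR strings into functional alleles."""
    positions = positions or load_pbr_positions()
    ztable = ztable if ztable is not None else load_zscales()
    groups: dict[str, list[str]] = {}
    for allele in sorted(aa_alleles, key=lambda a: a.id):
        pbr = extract_pbr(allele.aa, positions)
        groups.setdefault(pbr, []).append(allele.id)
    out = []
    for i, pbr in enumerate(sorted(groups), start=1):
        out.append(FunctionalAllele(id=f"FA{i:03d}", pbr=pbr, members=groups[pbr],
                                    z_matrix=encode_z(pbr, ztable)))
    return out


@dataclass
class FunctionalMap:
    """End-to-end DNA allele -> AA allele -> FA mapping for one allele set."""

    aa_alleles: list[AminoAcidAllele]
    fas: list[FunctionalAllele]
    dna_to_aa: dict[str, str] = field(default_factory=dict)
    aa_to_fa: dict[str, str] = field(default_factory=dict)

    @classmethod
    def build(cls, dna_alleles: dict[str, str],
              positions: list[int] | None = None,
              ztable: pd.DataFrame | None = None,
              fa_names: dict[str, str] | None = None) -> "FunctionalMap":
        aa_alleles = collapse_aa(dna_alleles)
        fas = collapse_functional(aa_alleles, positions, ztable)
        if fa_names:
            for fa in fas:
                if fa.pbr in fa_names:
                    fa.id = fa_names[fa.pbr]
        dna_to_aa = {m: a.id for a in aa_alleles for m in a.members}
        aa_to_fa = {m: f.id for f in fas for m in f.members}
        return cls(aa_alleles, fas, dna_to_aa, aa_to_fa)

    def fa_of_dna(self, dna_id: str) -> str:
        return self.aa_to_fa[self.dna_to_aa[dna_id]]

    def counts(self) -> tuple[int, int, int]:
        n_dna = len(self.dna_to_aa)
        return n_dna, len(self.aa_alleles), len(self.fas)


def fa_presence_and_frequency(genotypes: dict[str, set[str]],
                              fa_of_allele: dict[str, str],
                              cutoff: float = 0.10) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Per-individual FA presence/absence, FA carrier frequencies, and the
    common-FA list (frequency strictly above ``cutoff``).

    frequency(FA) = carriers / genotyped individuals.  Individuals with an
    empty genotype still count in the denominator only if present in
    ``genotypes`` with a non-empty set; failed samples should be omitted
    upstream.
    """
    unmapped = sorted({a for als in genotypes.values() for a in als}
                      - set(fa_of_allele))
    if unmapped:
        raise ValueError(f"alleles without FA assignment: {unmapped[:5]}"
                         + ("..." if len(unmapped) > 5 else ""))
    inds = sorted(genotypes)
    fa_sets = {ind: {fa_of_allele[a] for a in genotypes[ind]} for ind in inds}
    all_fas = sorted({fa for s in fa_sets.values() for fa in s})
    presence = pd.DataFrame(0, index=inds, columns=all_fas, dtype=int)
    for ind in inds:
        for fa in fa_sets[ind]:
            presence.loc[ind, fa] = 1
    freq = presence.mean(axis=0) if inds else pd.Series(dtype=float)
    common = sorted(freq.index[freq > cutoff])
    return presence, freq, common
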