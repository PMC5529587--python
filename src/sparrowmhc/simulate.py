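"""Synthetic aviary population with MHC genotypes, fitness effects and reads.

Generates pedigreed populations shaped like a captive house sparrow
breeding study: 14 aviaries of 4-5 breeding pairs, 1-4 clutches per female,
roughly 290 embryos in total; an MHC class I exon-3 allele pool of 85 DNA
alleles collapsing to 78 amino-acid alleles and 59 functional alleles (10
of them common, above 10% carrier frequency); planted functional-allele
effects on survival, body mass and tarsus; 10 neutral microsatellite loci;
and noisy tagged amplicon reads (unequal amplification, 1-bp substitution
errors, single-breakpoint chimeras, technical replicates, two runs).

Everything here is synthetic: sequences, allele names and effect sizes are
stand-ins calibrated to the published structure of the study system, not
real deposited data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .functional import load_pbr_positions, translate_allele
from .genotyping.matrix import RunMatrix, TagMap

FWD_PRIMER = "GTCTCCACACTGTACAGCGGC"
REV_PRIMER = "TGCGCTCCAGCTCCTTCTGCC"

# Codons are drawn from the parity code {xyz : x+y+z = 0 (mod 4) under
# A,C,G,T = 0..3}, whose members are pairwise >= 2 nt apart.  Together with
# globally unique substitution events this guarantees that no pool allele
# is a 1-bp variant or a single-breakpoint recombinant of other pool
# alleles, so artifact detection cannot be confounded by true alleles.
# The code covers 14 residues; leucine and arginine have two codons each,
# reserved for synonymous variants.
_CODON = {
    "A": "GCC", "C": "TGT", "E": "GAG", "G": "GGA", "H": "CAT",
    "I": "ATC", "K": "AAA", "L": "CTA", "P": "CCG", "R": "AGG",
    "S": "TCA", "T": "ACT", "V": "GTT", "Y": "TAC",
}
_SYN = {"L": "TTG", "R": "CGC"}
_RESIDUES = "ACEGHIKLPRSTVY"


@dataclass
class FAEffects:
    """Planted per-functional-allele effects (units: logit / g / mm)."""
    survival_logit_day1: float = 0.0
    survival_logit_day6: float = 0.0
    survival_logit_day12: float = 0.0
    mass_day6: float = 0.0
    mass_day12: float = 0.0
    tarsus_day6: float = 0.0
    tarsus_day12: float = 0.0


@dataclass
class ReadSimConfig:
    mean_coverage: float = 300.0
    dispersion: float = 10.0            # negative-binomial shape
    error_rate: float = 1e-3            # per base per read
    chimera_rate: float = 0.02          # per read
    amplification_sigma: float = 0.5    # log-normal allele skew
    runs: int = 2
    replicate_fraction: float = 0.13


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic aviary population."""
    seed: int = 0
    n_aviaries: int = 14
    pairs_per_aviary: tuple[int, int] = (4, 5)
    clutches_per_female: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.28, 3: 0.22, 4: 0.10})
    clutch_size_poisson_mean: float = 3.0      # eggs = 2 + Poisson(mean)
    embryo_rate: float = 0.325                 # embryos = 1 + Binom(eggs-1, rate)
    # allele pool structure: 85 DNA -> 78 AA -> 59 FA, 10 common
    n_dna_alleles: int = 85
    n_aa_alleles: int = 78
    n_fas: int = 59
    n_common_fas: int = 10
    common_allele_freq: float = 0.035
    effect_fa_carrier_freq: dict[str, float] = field(
        default_factory=lambda: {"FA25259": 0.1448, "FA18621": 0.1515})
    haplotype_size_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.35, 3: 0.35, 4: 0.15})
    effects: dict[str, FAEffects] = field(default_factory=lambda: {
        "FA25259": FAEffects(survival_logit_day6=-1.0,
                             mass_day6=-1.57, tarsus_day6=-0.67),
        "FA18621": FAEffects(tarsus_day12=0.68),
    })
    sharing_effect: float = -2.0    # day-6 survival logit per unit shared fraction
    sex_effect_day6: float = -0.5   # males (coded 1)
    clutch_order_effect_day1: float = -0.3
    clutch_size_effect_day12: float = -0.25
    surv_intercepts: dict[str, float] = field(default_factory=lambda: {
        "day1": 2.135, "day6": 1.47, "day12": 2.017})
    mass6_intercept: float = 14.5
    mass6_clutch_size: float = -0.5
    mass6_sd: float = 2.0
    tarsus6_intercept: float = 12.3
    tarsus6_clutch_order: float = -0.48
    tarsus6_sd: float = 1.0
    mass12_intercept: float = 24.0
    mass12_clutch_order: float = -1.43
    mass12_sd: float = 2.2
    tarsus12_intercept: float = 18.0
    tarsus12_clutch_order: float = -0.43
    tarsus12_sd: float = 0.9
    nonnatural_death_prob: float = 11.0 / 49.0
    sex_ratio: float = 0.5
    n_microsat_loci: int = 10
    n_microsat_alleles: int = 8
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)

    def validate(self) -> None:
        for name, dist in (("clutches_per_female", self.clutches_per_female),
                           ("haplotype_size_probs", self.haplotype_size_probs)):
            if abs(sum(dist.values()) - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} is not a probability distribution")
        if not set(self.clutches_per_female) <= {1, 2, 3, 4}:
            raise ValueError("clutches_per_female support must be within 1-4")
        if not set(self.haplotype_size_probs) <= {1, 2, 3, 4}:
            raise ValueError("haplotype sizes must be within 1-4")
        if not (self.n_fas <= self.n_aa_alleles <= self.n_dna_alleles):
            raise ValueError("need n_fas <= n_aa_alleles <= n_dna_alleles")
        if self.n_common_fas > self.n_fas:
            raise ValueError("more common FAs than FAs")
        if self.read_sim.mean_coverage < 104:
            raise ValueError("mean coverage below the m=8 genotyping-score "
                             "threshold of 104 reads")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0,1]")


# ---------------------------------------------------------------------------
# allele pool

@dataclass
class AllelePool:
    sequences: dict[str, str]            # DNA allele id -> 222 bp sequence
    frequencies: pd.Series               # per DNA allele, sums to 1
    aa_of_allele: dict[str, str]
    fa_of_allele: dict[str, str]
    fa_ids: list[str]
    common_fas: list[str]
    pbr_positions: list[int]

    def fa_set(self, dna_ids) -> set[str]:
        return {self.fa_of_allele[a] for a in dna_ids}


def build_allele_pool(config: SimConfig, rng: np.random.Generator) -> AllelePool:
    """Engineer a pool with the configured DNA -> AA -> FA collapse.

    Every allele is the shared base sequence plus a unique set of
    substitution events; no two alleles share an event (same codon index,
    same new residue), which — combined with the parity codon code — keeps
    all pool alleles at pairwise distance >= 2 and structurally
    non-chimeric with respect to one another.
    """
    positions = load_pbr_positions()
    n_codons = 74
    pbr0 = {p - 1 for p in positions}
    base_res = [str(r) for r in rng.choice(list(_RESIDUES), size=n_codons)]
    non_pbr = sorted(set(range(n_codons)) - pbr0)
    # synonymous variants need leucine/arginine codons to swap; guarantee
    # enough of them outside the PBR regardless of the random base draw
    n_syn_needed = config.n_dna_alleles - config.n_aa_alleles + 3
    lr_positions = [i for i in non_pbr if base_res[i] in _SYN]
    if len(lr_positions) < n_syn_needed:
        candidates = [i for i in non_pbr if base_res[i] not in _SYN]
        extra = rng.choice(candidates,
                           size=n_syn_needed - len(lr_positions), replace=False)
        for j, i in enumerate(extra):
            base_res[int(i)] = "L" if j % 2 == 0 else "R"
    base = [_CODON[r] for r in base_res]
    used_events: set[tuple[int, str]] = set()

    def substitute(codons: list[str], pos0: int) -> list[str]:
        """Apply a globally unique substitution event at codon pos0."""
        current = translate_allele(codons[pos0])
        choices = [r for r in _RESIDUES
                   if r != current and r != base_res[pos0]
                   and (pos0, r) not in used_events]
        if not choices:
            raise RuntimeError(f"substitution capacity exhausted at codon {pos0}")
        new = str(rng.choice(choices))
        used_events.add((pos0, new))
        out = list(codons)
        out[pos0] = _CODON[new]
        return out

    effect_names = list(config.effect_fa_carrier_freq)
    fa_ids = effect_names + [f"FA{i:05d}" for i in range(1, config.n_fas - len(effect_names) + 1)]
    common = fa_ids[:config.n_common_fas]

    def has_capacity(pos0: int) -> bool:
        return any(r != base_res[pos0] and (pos0, r) not in used_events
                   for r in _RESIDUES)

    # one founder AA sequence per FA, distinct at the PBR
    used_pbr: set[str] = set()
    fa_codons: dict[str, list[str]] = {}
    for fa in fa_ids:
        cand = list(base)
        avail = [p for p in sorted(pbr0) if has_capacity(p)]
        k = min(int(rng.integers(1, 4)), len(avail))
        for pos in rng.choice(avail, size=k, replace=False):
            cand = substitute(cand, int(pos))
        pbr = "".join(translate_allele("".join(cand))[p - 1] for p in positions)
        if pbr in used_pbr:
            raise RuntimeError("PBR collision despite unique events")
        used_pbr.add(pbr)
        fa_codons[fa] = cand

    # extra AA members: mutate a non-PBR residue (PBR string unchanged)
    n_extra_aa = config.n_aa_alleles - config.n_fas
    aa_seqs: dict[str, tuple[str, list[str]]] = {}   # aa key -> (fa, codons)
    for fa in fa_ids:
        aa_seqs[translate_allele("".join(fa_codons[fa]))] = (fa, fa_codons[fa])
    extra_parents = [str(x) for x in rng.choice(fa_ids[config.n_common_fas:],
                                                size=n_extra_aa, replace=False)]
    for fa in extra_parents:
        pos = int(rng.choice(non_pbr))
        cand = substitute(fa_codons[fa], pos)
        aa = translate_allele("".join(cand))
        if aa in aa_seqs:
            raise RuntimeError("AA collision despite unique events")
        aa_seqs[aa] = (fa, cand)

    # DNA alleles: one per AA sequence, plus synonymous variants made by
    # swapping a leucine/arginine codon to its alternate parity codon at a
    # position not used by any other synonymous swap
    dna: dict[str, tuple[str, str]] = {}             # dna seq -> (fa, aa)
    for aa, (fa, codons) in aa_seqs.items():
        dna["".join(codons)] = (fa, aa)
    n_syn = config.n_dna_alleles - config.n_aa_alleles
    syn_donor_fas = [str(x) for x in rng.choice(common, size=n_syn,
                                                replace=len(common) < n_syn)]
    syn_used: set[int] = set()
    for fa in syn_donor_fas:
        codons = fa_codons[fa]
        swappable = [i for i, c in enumerate(codons)
                     if translate_allele(c) in _SYN and c == _CODON[translate_allele(c)]
                     and i not in syn_used]
        if not swappable:
            raise RuntimeError("no synonymous swap position available")
        i = int(rng.choice(swappable))
        syn_used.add(i)
        cand = list(codons)
        cand[i] = _SYN[translate_allele(cand[i])]
        seq = "".join(cand)
        if seq in dna:
            raise RuntimeError("DNA collision despite unique swap positions")
        dna[seq] = (fa, translate_allele(seq))

    # name and weight the DNA alleles
    seqs_sorted = sorted(dna)
    ids = {seq: f"Pado-SYN_{i + 1:03d}" for i, seq in enumerate(seqs_sorted)}
    sequences = {ids[s]: s for s in seqs_sorted}
    aa_of = {ids[s]: dna[s][1] for s in seqs_sorted}
    fa_of = {ids[s]: dna[s][0] for s in seqs_sorted}

    # FA-level frequencies, split evenly across member DNA alleles
    mean_hap = sum(k * p for k, p in config.haplotype_size_probs.items())
    fa_freq: dict[str, float] = {}
    for fa, carrier in config.effect_fa_carrier_freq.items():
        hap_freq = 1.0 - np.sqrt(1.0 - carrier)
        fa_freq[fa] = hap_freq / mean_hap
    for fa in common:
        fa_freq.setdefault(fa, config.common_allele_freq)
    rest = 1.0 - sum(fa_freq.values())
    n_rare = len(fa_ids) - len(common)
    for fa in fa_ids[config.n_common_fas:]:
        fa_freq[fa] = rest / n_rare

    members: dict[str, list[str]] = {}
    for aid, fa in fa_of.items():
        members.setdefault(fa, []).append(aid)
    freq = {}
    for fa, mem in members.items():
        for aid in mem:
            freq[aid] = fa_freq[fa] / len(mem)
    frequencies = pd.Series(freq).reindex(sorted(sequences)).astype(float)
    frequencies /= frequencies.sum()

    return AllelePool(sequences=sequences, frequencies=frequencies,
                      aa_of_allele=aa_of, fa_of_allele=fa_of,
                      fa_ids=fa_ids, common_fas=common,
                      pbr_positions=positions)


# ---------------------------------------------------------------------------
# population

@dataclass
class TruePopulation:
    individuals: pd.DataFrame
    allele_sets: dict[str, set[str]]
    fa_sets: dict[str, set[str]]
    pairs: pd.DataFrame
    microsats: pd.DataFrame
    pool: AllelePool
    config: SimConfig


def _draw_from(dist: dict[int, float], rng: np.random.Generator) -> int:
    ks = sorted(dist)
    return int(rng.choice(ks, p=[dist[k] for k in ks]))


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def simulate_population(config: SimConfig | None = None) -> TruePopulation:
    """Simulate parents, pedigree, genotypes and phenotypes.

    Reproducible for a fixed seed.  Survival is Bernoulli under a logistic
    model (planted FA, sharing, sex and clutch effects on centred
    covariates); mass and tarsus are Gaussian.  Phenotypes are missing for
    individuals dead before the measurement day; survival is monotone
    across days.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    pool = build_allele_pool(config, rng)
    allele_ids = list(pool.frequencies.index)
    # designated effect alleles are seeded into the parental haplotype pool
    # at their target frequency below, so the base draw excludes them; this
    # pins realized carrier frequencies near their emulation targets instead
    # of letting them drift with the small founder pool
    effect_members = {fa: sorted(a for a in allele_ids
                                 if pool.fa_of_allele[a] == fa)
                      for fa in config.effect_fa_carrier_freq}
    seeded = {a for mem in effect_members.values() for a in mem}
    p = pool.frequencies.copy()
    p[list(seeded)] = 0.0
    p = (p / p.sum()).to_numpy()

    def draw_haplotype() -> frozenset:
        k = _draw_from(config.haplotype_size_probs, rng)
        return frozenset(str(a) for a in
                         rng.choice(allele_ids, size=k, replace=False, p=p))

    msat_sizes = {f"L{j + 1:02d}": [100 + 2 * a for a in range(config.n_microsat_alleles)]
                  for j in range(config.n_microsat_loci)}
    msat_freq = np.arange(1, config.n_microsat_alleles + 1, dtype=float)
    msat_freq /= msat_freq.sum()

    individuals: list[dict] = []
    allele_sets: dict[str, set[str]] = {}
    fa_sets: dict[str, set[str]] = {}
    haplotypes: dict[str, tuple[frozenset, frozenset]] = {}
    msat_rows: list[dict] = []
    msat_geno: dict[str, dict[str, tuple[int, int]]] = {}
    pairs: list[dict] = []

    def add_parent(ind: str, sex: str, aviary: str) -> None:
        h1, h2 = draw_haplotype(), draw_haplotype()
        haplotypes[ind] = (h1, h2)
        allele_sets[ind] = set(h1 | h2)
        fa_sets[ind] = pool.fa_set(allele_sets[ind])
        geno = {}
        for locus, sizes in msat_sizes.items():
            a, b = rng.choice(sizes, size=2, replace=True, p=msat_freq)
            geno[locus] = (int(a), int(b))
            msat_rows.append({"individual": ind, "locus": locus,
                              "a1": int(a), "a2": int(b)})
        msat_geno[ind] = geno
        individuals.append({"individual": ind, "role": "parent", "sex": sex,
                            "aviary": aviary, "mother": "", "father": "",
                            "clutch_id": "", "clutch_order": np.nan,
                            "clutch_size": np.nan})

    # pass 1: breeding pairs and parental haplotypes
    pair_idx = 0
    for av in range(config.n_aviaries):
        aviary = f"AV{av + 1:02d}"
        n_pairs = int(rng.integers(config.pairs_per_aviary[0],
                                   config.pairs_per_aviary[1] + 1))
        for _ in range(n_pairs):
            pair_idx += 1
            male, female = f"M{pair_idx:03d}", f"F{pair_idx:03d}"
            add_parent(male, "M", aviary)
            add_parent(female, "F", aviary)
            pairs.append({"pair_id": f"{female}|{male}", "male": male,
                          "female": female, "aviary": aviary})

    # pass 2: seed designated effect alleles into parental haplotypes at
    # their target haplotype frequency (replace one resident allele so
    # haplotype sizes stay within 1-4)
    parent_ids = sorted(haplotypes)
    slots = [(ind, j) for ind in parent_ids for j in (0, 1)]
    for fa, carrier in config.effect_fa_carrier_freq.items():
        hap_freq = 1.0 - float(np.sqrt(1.0 - carrier))
        n_assign = min(len(slots), int(round(hap_freq * len(slots))))
        chosen = rng.choice(len(slots), size=n_assign, replace=False)
        for idx in chosen:
            ind, j = slots[int(idx)]
            hap = sorted(haplotypes[ind][j])   # stable order across processes
            allele = str(effect_members[fa][int(rng.integers(len(effect_members[fa])))])
            # never displace an already-seeded effect allele
            replaceable = [k for k, a in enumerate(hap) if a not in seeded]
            if replaceable:
                hap[replaceable[int(rng.integers(len(replaceable)))]] = allele
            else:
                hap.append(allele)
            hs = list(haplotypes[ind])
            hs[j] = frozenset(hap)
            haplotypes[ind] = tuple(hs)
    for ind in parent_ids:
        allele_sets[ind] = set(haplotypes[ind][0] | haplotypes[ind][1])
        fa_sets[ind] = pool.fa_set(allele_sets[ind])

    # pass 3: clutches and offspring
    offspring_idx = 0
    for pair in pairs:
        male, female, aviary = pair["male"], pair["female"], pair["aviary"]
        shared_frac = _prop_shared(fa_sets[male], fa_sets[female]) / 100.0
        n_clutches = _draw_from(config.clutches_per_female, rng)
        if n_clutches:
            for order in range(1, n_clutches + 1):
                clutch_id = f"{female}c{order}"
                eggs = 2 + int(rng.poisson(config.clutch_size_poisson_mean))
                n_embryos = 1 + int(rng.binomial(eggs - 1, config.embryo_rate))
                for _ in range(n_embryos):
                    offspring_idx += 1
                    ind = f"O{offspring_idx:04d}"
                    hm = haplotypes[male][int(rng.integers(2))]
                    hf = haplotypes[female][int(rng.integers(2))]
                    alleles = set(hm | hf)
                    fas = pool.fa_set(alleles)
                    allele_sets[ind] = alleles
                    fa_sets[ind] = fas
                    sex = "M" if rng.random() < config.sex_ratio else "F"
                    geno = {}
                    for locus in msat_sizes:
                        am = msat_geno[male][locus][int(rng.integers(2))]
                        af = msat_geno[female][locus][int(rng.integers(2))]
                        geno[locus] = (am, af)
                        msat_rows.append({"individual": ind, "locus": locus,
                                          "a1": am, "a2": af})
                    msat_geno[ind] = geno

                    fa_eff = {k: 0.0 for k in vars(FAEffects())}
                    for fa in sorted(fas):   # stable float-summation order
                        eff = config.effects.get(fa)
                        if eff:
                            for k in fa_eff:
                                fa_eff[k] += getattr(eff, k)
                    sex01 = 1.0 if sex == "M" else 0.0
                    logit1 = (config.surv_intercepts["day1"]
                              + config.clutch_order_effect_day1 * (order - 2.0)
                              + fa_eff["survival_logit_day1"])
                    s1 = int(rng.random() < _logistic(logit1))
                    logit6 = (config.surv_intercepts["day6"]
                              + config.sharing_effect * (shared_frac - 0.12)
                              + config.sex_effect_day6 * (sex01 - 0.5)
                              + fa_eff["survival_logit_day6"])
                    s6 = int(s1 and rng.random() < _logistic(logit6))
                    logit12 = (config.surv_intercepts["day12"]
                               + config.clutch_size_effect_day12 * (eggs - 5.0)
                               + fa_eff["survival_logit_day12"])
                    s12 = int(s6 and rng.random() < _logistic(logit12))
                    nonnat = int(s1 == 1 and s6 == 0
                                 and rng.random() < config.nonnatural_death_prob)

                    def gauss(mu: float, sd: float) -> float:
                        return float(mu + sd * rng.standard_normal())

                    mass6 = (gauss(config.mass6_intercept
                                   + config.mass6_clutch_size * (eggs - 5.0)
                                   + fa_eff["mass_day6"], config.mass6_sd)
                             if s6 else np.nan)
                    tarsus6 = (gauss(config.tarsus6_intercept
                                     + config.tarsus6_clutch_order * (order - 2.0)
                                     + fa_eff["tarsus_day6"], config.tarsus6_sd)
                               if s6 else np.nan)
                    mass12 = (gauss(config.mass12_intercept
                                    + config.mass12_clutch_order * (order - 2.0)
                                    + fa_eff["mass_day12"], config.mass12_sd)
                              if s12 else np.nan)
                    tarsus12 = (gauss(config.tarsus12_intercept
                                      + config.tarsus12_clutch_order * (order - 2.0)
                                      + fa_eff["tarsus_day12"], config.tarsus12_sd)
                                if s12 else np.nan)
                    individuals.append({
                        "individual": ind, "role": "offspring", "sex": sex,
                        "aviary": aviary, "mother": female, "father": male,
                        "clutch_id": clutch_id, "clutch_order": order,
                        "clutch_size": eggs,
                        "survived_day1": s1, "survived_day6": s6,
                        "survived_day12": s12, "nonnatural_death": nonnat,
                        "mass_day6": mass6, "mass_day12": mass12,
                        "tarsus_day6": tarsus6, "tarsus_day12": tarsus12,
                    })

    inds = pd.DataFrame(individuals)
    return TruePopulation(individuals=inds, allele_sets=allele_sets,
                          fa_sets=fa_sets, pairs=pd.DataFrame(pairs),
                          microsats=pd.DataFrame(msat_rows), pool=pool,
                          config=config)


def _prop_shared(a: set, b: set) -> float:
    return 100.0 / (len(a) + len(b)) * len(a & b)


# ---------------------------------------------------------------------------
# amplicon reads

def _make_tags(n: int, rng: np.random.Generator) -> list[str]:
    tags: list[str] = []
    seen = set()
    while len(tags) < n:
        tag = "".join(rng.choice(list("ACGT"), size=8))
        if tag not in seen:
            seen.add(tag)
            tags.append(tag)
    return tags


def simulate_reads(pop: TruePopulation,
                   config: SimConfig | None = None) -> tuple[list[RunMatrix], TagMap]:
    """Simulate per-run sample x variant read counts with noise.

    Per-sample totals are negative-binomial around the mean coverage;
    reads are allocated to the sample's true alleles with log-normal
    amplification weights; the error process converts reads into 1-bp
    substitution variants; the chimera process emits single-breakpoint
    recombinants of two of the sample's alleles.  A configured fraction of
    samples is re-simulated independently as linked technical replicates.
    """
    config = config or pop.config
    rs = config.read_sim
    if rs.mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    rng = np.random.default_rng(config.seed + 1_000_003)
    seqs = pop.pool.sequences

    individuals = sorted(pop.allele_sets)
    for ind in individuals:
        if not pop.allele_sets[ind]:
            raise ValueError(f"individual {ind} has no true alleles")
    # whole families share a run: the two-independent-PCRs filter relies on
    # pedigree sharing, which only helps when relatives are filtered together
    fam_of: dict[str, str] = {}
    for _, pr in pop.pairs.iterrows():
        fam_of[pr["male"]] = fam_of[pr["female"]] = pr["pair_id"]
    off = pop.individuals[pop.individuals["role"] == "offspring"]
    for _, row in off.iterrows():
        fam_of[row["individual"]] = f"{row['mother']}|{row['father']}"
    families = sorted({fam_of.get(i, i) for i in individuals})
    fam_run = {fam: i % rs.runs for i, fam in enumerate(families)}
    run_of: dict[str, int] = {ind: fam_run[fam_of.get(ind, ind)]
                              for ind in individuals}

    matrices: list[RunMatrix] = []
    tag_rows: list[dict] = []
    for run in range(rs.runs):
        run_id = f"R{run + 1}"
        members = [ind for ind in individuals if run_of[ind] == run]
        n_rep = int(round(rs.replicate_fraction * len(members)))
        reps = list(rng.choice(members, size=n_rep, replace=False)) if n_rep else []
        samples = [(ind, ind) for ind in members] + [(f"{ind}.rep", ind) for ind in reps]

        counts: dict[str, dict[str, int]] = {}
        for sample, ind in samples:
            alleles = sorted(pop.allele_sets[ind])
            L = len(seqs[alleles[0]])
            total = int(rng.poisson(rng.gamma(rs.dispersion,
                                              rs.mean_coverage / rs.dispersion)))
            weights = np.exp(rng.normal(0.0, rs.amplification_sigma, len(alleles)))
            alloc = rng.multinomial(total, weights / weights.sum())
            cc: dict[str, int] = {}
            for aid, n_reads in zip(alleles, alloc):
                if n_reads == 0:
                    continue
                n_chim = rng.binomial(n_reads, rs.chimera_rate) if len(alleles) > 1 else 0
                p_err = 1.0 - (1.0 - rs.error_rate) ** L
                n_err = rng.binomial(n_reads - n_chim, p_err)
                n_clean = n_reads - n_chim - n_err
                if n_clean:
                    cc[seqs[aid]] = cc.get(seqs[aid], 0) + int(n_clean)
                for _ in range(int(n_err)):
                    pos = int(rng.integers(L))
                    base = seqs[aid][pos]
                    alt = rng.choice([b for b in "ACGT" if b != base])
                    var = seqs[aid][:pos] + alt + seqs[aid][pos + 1:]
                    cc[var] = cc.get(var, 0) + 1
                for _ in range(int(n_chim)):
                    other = rng.choice([a for a in alleles if a != aid])
                    bp = int(rng.integers(1, L))
                    var = seqs[aid][:bp] + seqs[other][bp:]
                    cc[var] = cc.get(var, 0) + 1
            counts[sample] = cc

        all_seqs = sorted({s for cc in counts.values() for s in cc})
        vids = {s: f"var{i + 1:05d}" for i, s in enumerate(all_seqs)}
        mat = pd.DataFrame(0, index=sorted(counts), columns=[vids[s] for s in all_seqs],
                           dtype=int)
        for sample, cc in counts.items():
            for s, n in cc.items():
                mat.loc[sample, vids[s]] = n
        links = [(ind, f"{ind}.rep") for ind in reps]
        matrices.append(RunMatrix(run_id=run_id, counts=mat,
                                  sequences={v: s for s, v in vids.items()},
                                  replicate_links=links))
        tags = _make_tags(len(samples), rng)
        for tag, (sample, ind) in zip(tags, samples):
            tag_rows.append({"tag": tag, "sample": sample, "run": run_id,
                             "replicate_of": ind if sample.endswith(".rep") else ""})

    tag_table = pd.DataFrame(tag_rows)
    # tags must be globally unique for unambiguous demultiplexing
    while tag_table["tag"].duplicated().any():
        dup = tag_table["tag"].duplicated()
        fresh = _make_tags(int(dup.sum()) + 8, rng)
        pool_iter = (t for t in fresh if t not in set(tag_table["tag"]))
        tag_table.loc[dup, "tag"] = [next(pool_iter) for _ in range(int(dup.sum()))]
    return matrices, TagMap(tag_table)


def sample_to_individual(tag_map: TagMap) -> dict[str, str]:
    out = {}
    for _, row in tag_map.table.iterrows():
        out[row["sample"]] = row["replicate_of"] or row["sample"]
    return out


def write_reads_fasta(matrices: list[RunMatrix], tag_map: TagMap, out_dir,
                      fwd_primer: str = FWD_PRIMER,
                      rev_primer: str = REV_PRIMER) -> list[Path]:
    """Emit one reads FASTA per run with tag + primers around each variant."""
    from Bio.Seq import Seq

    rev_rc = str(Seq(rev_primer).reverse_complement())
    out_dir = Path(out_dir)
    paths = []
    for mat in matrices:
        run_tags = tag_map.for_run(mat.run_id)
        tag_of = dict(zip(run_tags["sample"], run_tags["tag"]))
        path = out_dir / f"reads_{mat.run_id}.fasta"
        with open(path, "w") as fh:
            n = 0
            for sample in mat.counts.index:
                row = mat.counts.loc[sample]
                for vid in row.index[row > 0]:
                    seq = tag_of[sample] + fwd_primer + mat.sequences[vid] + rev_rc
                    for _ in range(int(row[vid])):
                        n += 1
                        fh.write(f">{tag_of[sample]}|read{n}\n{seq}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# fixture trees and fixture writing

def upgma_newick(labels: list[str], dist: np.ndarray) -> str:
    """Rooted ultrametric tree (average linkage) in Newick, for fixtures."""
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    if len(labels) == 1:
        return f"({labels[0]}:0.0):0.0;"
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    tree = hierarchy.to_tree(Z)

    def rec(node) -> tuple[str, float]:
        if node.is_leaf():
            return labels[node.id], 0.0
        left, lh = rec(node.left)
        right, rh = rec(node.right)
        h = node.dist / 2.0
        return f"({left}:{h - lh:.6f},{right}:{h - rh:.6f})", h

    s, _ = rec(tree)
    return s + ";"


def fixture_trees(pool: AllelePool) -> tuple[str, str]:
    """Simple distance trees over the pool: DNA alleles (Hamming) and
    functional alleles (Euclidean on flattened z-matrices)."""
    from .functional import encode_z

    ids = sorted(pool.sequences)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pool.sequences[ids[i]], pool.sequences[ids[j]]
            d[i, j] = d[j, i] = (sum(x != y for x, y in zip(a, b))
                                 + abs(len(a) - len(b)))
    allele_tree = upgma_newick(ids, d)

    fa_pbr: dict[str, str] = {}
    for aid in ids:
        fa = pool.fa_of_allele[aid]
        aa = pool.aa_of_allele[aid]
        fa_pbr[fa] = "".join(aa[p - 1] for p in pool.pbr_positions)
    fa_ids = sorted(fa_pbr)
    zmats = {fa: encode_z(fa_pbr[fa]).ravel() for fa in fa_ids}
    m = len(fa_ids)
    df = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            df[i, j] = df[j, i] = float(np.linalg.norm(zmats[fa_ids[i]] - zmats[fa_ids[j]]))
    fa_tree = upgma_newick(fa_ids, df)
    return allele_tree, fa_tree


def write_fixtures(pop: TruePopulation, out_dir,
                   matrices: list[RunMatrix] | None = None,
                   tag_map: TagMap | None = None,
                   write_reads: bool = False) -> dict:
    """Write the complete fixture set plus a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "alleles.fasta", "w") as fh:
        for aid in sorted(pop.pool.sequences):
            fh.write(f">{aid} fa={pop.pool.fa_of_allele[aid]} synthetic\n"
                     f"{pop.pool.sequences[aid]}\n")
    pop.individuals.to_csv(out / "pedigree_phenotypes.tsv", sep="\t", index=False)
    pop.microsats.to_csv(out / "microsatellites.tsv", sep="\t", index=False)
    pop.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    geno_rows = [{"individual": ind, "allele": a}
                 for ind in sorted(pop.allele_sets)
                 for a in sorted(pop.allele_sets[ind])]
    pd.DataFrame(geno_rows).to_csv(out / "true_genotypes.tsv", sep="\t", index=False)
    allele_tree, fa_tree = fixture_trees(pop.pool)
    (out / "allele_tree.nwk").write_text(allele_tree + "\n")
    (out / "fa_tree.nwk").write_text(fa_tree + "\n")
    if tag_map is not None:
        tag_map.write_tsv(out / "tag_map.tsv")
    if matrices is not None:
        for mat in matrices:
            mat.write_tsv(out / f"counts_{mat.run_id}.tsv")
            with open(out / f"variants_{mat.run_id}.fasta", "w") as fh:
                for vid in sorted(mat.sequences):
                    fh.write(f">{vid}\n{mat.sequences[vid]}\n")
        if write_reads and tag_map is not None:
            write_reads_fasta(matrices, tag_map, out)

    manifest = {"seed": pop.config.seed, "files": {}}
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][path.name] = digest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
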