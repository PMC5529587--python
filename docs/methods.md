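# Methods

This package reimplements, as one tested pipeline, the computational path
of an aviary study of house sparrows (*Passer domesticus*) relating MHC
class I functional diversity to nestling survival and growth: amplicon
genotype calling, functional-allele coding, parental similarity, and an
information-theoretic variable-selection analysis. A synthetic-data
generator stands in for the study's raw data, so every stage is testable
end to end.

## Genotype calling from tagged amplicon reads

MHC class I exon 3 (222–225 bp) is amplified with tagged primers and
sequenced to a target depth of ~300 reads per sample across two runs that
are filtered separately. Demultiplexing requires a complete, exact tag and
both primers; tag and primers are stripped and identical sequences within
a sample are merged.

The filter cascade, in order:

1. **Low abundance** — per-sample variant cells with < 3 reads are zeroed.
2. **Coverage** — samples are retained only if their total reads reach the
   threshold from the *genotyping score*: the probability, under a
   multinomial model with `m` equally amplified alleles, that every allele
   receives at least `t` of `T` reads. The score is computed exactly by
   big-integer dynamic programming over alleles (number of ordered
   read-to-allele assignments in which each allele appears ≥ t times,
   divided by `m^T`), and the threshold is the smallest `T` whose score
   reaches the requested confidence. For house sparrows (at most eight
   classical class I alleles), `m = 8`, `t = 3` and 99.9% confidence give
   a threshold of 104 reads: score(103) = 0.99895 < 0.999 ≤
   score(104) = 0.99907.
3. **Within-sample frequency** — variants below 2% of their sample's total
   are removed, in a single pass over the totals entering this step (so the
   outcome does not depend on the order cells are visited).
4. **Occurrence** — every variant must occur in at least two samples of the
   run; technical replicates count as independent PCRs.
5. **Length and frame** — variants outside 222–225 bp, or whose length
   difference from the 222-bp reference is not a whole number of codons,
   are dropped. (Note 223/224 bp can never pass the codon-phase rule; both
   rules are kept configurable.)
6. **Artifacts** — variants are examined from the rarest upward. A variant
   is a 1-bp artifact if an unflagged equal-length variant at Hamming
   distance 1 has at least 10× its population read count, and a chimera if
   it equals `prefix(u1) + suffix(u2)` at a single breakpoint for two
   unflagged parents each with ≥ 10× its count. Variants at ≥ 2%
   population frequency are treated as true alleles (audit mode examines
   them anyway). The ratio rule replaces by-eye checking for the sake of
   reproducibility; flagged variants are logged, and flagged variants
   cannot serve as parents of later decisions.

Replicates and runs are reconciled by union of accepted calls (the
occurrence filter has already demanded independent support); an
intersection mode exists for sensitivity analysis.

## Functional alleles

Filtered DNA alleles are translated (standard code, frame anchored to the
222-bp reference; internal stops are rejected) and grouped into amino-acid
alleles by identical translation. The 16 residues homologous to the
chicken class I peptide-binding region (PBR) are extracted and encoded
with the five published physicochemical z-descriptors per residue
(z1 hydrophobicity, z2 steric bulk, z3 polarity, z4/z5 electronic
effects), giving a 16 × 5 matrix. Amino-acid alleles with identical PBR
strings form one *functional allele* (FA).

FA identity is exact PBR-string equality: it yields a deterministic
collapse without an arbitrary clustering radius (a z-space
threshold-clustering mode exists but is off by default). The 16 PBR codon
positions ship as a data file — they are a homology-motivated default, not
an inferred alignment, and should be replaced by a study-specific list
when one is available; on real data the collapse counts are the natural
calibration check.

Carrier frequency of an FA is the fraction of genotyped individuals
carrying any member allele; FAs above a 10% cutoff (configurable) enter
the statistical analysis as presence/absence predictors.

## Parental similarity and neutral heterozygosity

* Proportion of FAs shared: `100 / (n_male + n_female) × n_shared`, with
  sets (shared alleles counted once), so identical parents score 50. A
  `count_both` flag doubles the numerator for sensitivity analysis.
* Tree distances: unweighted UniFrac between the parents' leaf sets on a
  rooted allele tree and on a functional-allele tree supplied as Newick
  (tree inference itself is out of scope; fixture trees are built by
  average-linkage clustering of Hamming / z-matrix distances). UniFrac is
  the branch length subtending exactly one of the two sets divided by the
  branch length subtending either; zero-length branches contribute
  nothing, multifurcations are allowed.
* Multilocus heterozygosity: heterozygous typed loci / typed loci over 10
  neutral microsatellites, missing loci excluded from both counts.

## Statistical analysis

Responses: survival at day 1 (hatching), day 6 and day 12; body mass and
tarsus length at days 6 and 12. Candidate predictors: clutch size, clutch
order, sex, heterozygosity, FA count, presence/absence of the common FAs,
and (survival only) the three parental-similarity measures — 15–19
variables against 190–290 observations, an overfitting risk that rules
out a single full model.

Survival responses are aggregated to clutch means (survival becomes the
clutch's survival proportion, sex the sex ratio) — the route taken when
per-individual logistic mixed models fail to converge, which is typical at
these sizes; a per-individual logistic backend exists behind a flag.
Aggregated fits are weighted by clutch size, since a mean of `n` chicks
has variance `σ²/n`; day-of-season is dropped in favour of clutch order
(the two are strongly collinear in a synchronized season; the correlation
is computed and logged when a day column is present). Chicks whose death
was non-natural (e.g. killed by neighbouring adults) are excluded from the
day-6 survival risk set.

Selection proceeds by rotation: all subsets (2^k models, intercept-only
included) of the first ten variables are fitted; AICc
(`−2 logL + 2k + 2k(k+1)/(n−k−1)`) gives Akaike weights
`w_i ∝ exp(−Δ_i/2)`, and each variable's RVI is the summed weight of
models containing it. Variables with RVI > 0.5 stay; the pool is refilled
with the next unused variables to ten, and so on until every variable has
entered a pool. A final all-subsets fit over the kept variables is
model-averaged in full (absent coefficients enter as zero) with the
revised unconditional variance for the adjusted SE:
`SE(v) = sqrt(Σ w_i (var_iv + (β_iv − β̄_v)²))`; p-values are two-sided
normal. Variables with final RVI > 0.7 are flagged relevant. The default
fitting backend is Gaussian maximum likelihood (fixed effects; `k` counts
coefficients plus the residual variance); a nested random-intercept
MixedLM backend (female within aviary) satisfies the same contract but is
orders of magnitude slower across thousands of candidate fits, so it is
not the default. The final interpretation model refits all kept variables
jointly and re-averages; models with undefined AICc (n ≤ k+1) or failed
convergence are retained in the candidate list but excluded from weights.

## The synthetic-data generator

The generator emulates the study design: 14 aviaries × 4–5 breeding
pairs; 1–4 clutches per female (probabilities 0.40/0.28/0.22/0.10); clutch
sizes of 2 + Poisson(3) eggs of which 1 + Binomial(eggs−1, 0.325) are
analysed embryos — about 290 offspring from ~60 families. Each parent
carries two haplotypes of 1–4 DNA alleles (so offspring carry 1–8); one
haplotype is transmitted per meiosis. This haplotype model is a stand-in:
the true locus structure behind 1–8 alleles per individual is unknown.

The allele pool is engineered to collapse 85 DNA → 78 AA → 59 FA: 59
founders distinct at the PBR, 19 extra members differing at a non-PBR
residue, 7 synonymous variants. All codons come from a parity code
(pairwise ≥ 2 nt apart at a position) and every substitution event
(position, residue) is globally unique, which guarantees no pool allele is
a 1-bp variant or a single-breakpoint recombinant of others — so artifact
detection is exercised only by actual simulated artifacts. Ten FAs are
common; the two designated effect alleles are seeded into parental
haplotypes at the haplotype frequency that yields their target offspring
carrier frequencies (14.48% and 15.15%), replacing founder drift — which
at ~250 founder haplotypes would otherwise swamp the calibration — with
Mendelian transmission noise only.

Planted effects (defaults): one FA lowers day-6 survival by 1.0 logit,
day-6 mass by 1.57 g and day-6 tarsus by 0.67 mm; the other raises day-12
tarsus by 0.68 mm; proportion shared lowers day-6 survival (−2.0 logit per
unit shared fraction); males −0.5 logit at day 6; clutch order −0.3
(day 1); clutch size −0.25 (day 12). Survival intercepts are set so the
expected mortality schedule matches the study's (≈ 10.6% unhatched, 18.7%
dead by day 6 of which 22.4% non-natural, 11.7% dead by day 12). Baseline
phenotypes: mass 14.5 ± 2.0 g and tarsus 12.3 ± 1.0 mm at day 6; 24.0 ±
2.2 g and 18.0 ± 0.9 mm at day 12. Survival is monotone across days and
phenotypes are missing after death.

Reads: per-sample totals are gamma-Poisson around 300 (shape 10); reads
are allocated to alleles with log-normal weights (σ = 0.5, stressing the
2% filter); errors substitute one random base per affected read
(per-base rate 10⁻³); chimeras recombine two of the sample's alleles at a
uniform breakpoint (rate 0.02); ~13% of samples are re-simulated as linked
technical replicates. Families share a run: the two-PCR occurrence
criterion leans on pedigree sharing, which only operates when relatives
are filtered together. In the zero-noise oracle configuration every
sample is replicated, because exact recovery is only the correct
expectation when every true allele is observable in two independent PCRs
(a singleton allele in a single PCR *should* be removed by the occurrence
filter).

What the generator does not emulate: 454 homopolymer error profiles,
indel errors, extra-pair paternity, shared environmental (weather/season)
effects, and linkage between MHC and other loci. Passing tests therefore
demonstrate the pipeline's correctness under the stated noise model, not
robustness to every artifact class of real 454 data.

## Numerical choices and problem sizes

Exact rational arithmetic for the genotyping score (no floating-point
threshold ambiguity); single-pass 2% filter; artifact sweep in ascending
frequency with deterministic tie-breaks by variant id; weighted least
squares solved by Cholesky on the Gram matrix with pseudo-inverse
fallback. Statistical property checks run at the study's scale: planted
effect recovery uses 50 replicate populations of ~250 clutches; null
calibration uses 100; the end-to-end genotyping check uses ~460 samples
at 300× coverage. All simulation is hash-seed independent: set iterations
that feed randomness or float accumulation are explicitly ordered, so a
fixed seed gives byte-identical populations across processes.

Power at these sizes is marginal by design of the study itself: a −1.0
logit day-6 survival effect on a ~15%-frequency allele is flagged
(final RVI > 0.7) in 80% of replicates when it is the only planted
effect on that response, and in ~74% when the sharing and sex effects
compete on the same response — the rotation procedure sits right at the
edge of what ~250 clutches can resolve. Null calibration is checked by
significance test: no variable's null exceedance rate may significantly
exceed 0.10 (the maximum observed over 19 variables is expected to
overshoot a hard 0.10 cut about half the time even under perfect
calibration).

## Known limitations

* PBR positions are a documented default, not an inferred alignment.
* z-scale constants are embedded from the published five-descriptor table;
  only their distinctness matters for FA identity.
* The mixed-model backend fits a single nested random-intercept structure;
  REML, crossed effects and convergence-tuning are out of scope.
* Length-variant (225 bp) alleles are handled by codon-preserving
  anchoring only for the C-terminal insertion case; the synthetic pool is
  uniformly 222 bp.
* The CLI covers the common paths; unusual combinations (e.g. custom
  filter order) are library-only.
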