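# sparrowmhc

MHC class I amplicon genotyping, functional-allele coding and AICc/RVI
survival analysis for pedigreed house sparrow (*Passer domesticus*)
aviary populations.

Embryo and nestling mortality in house sparrows can exceed 50%, and part
of that variation may be genetic: the highly polymorphic MHC class I
genes determine which pathogen peptides can be presented to T cells.
This package implements, as one tested pipeline, the computational path
of an aviary breeding study relating MHC functional diversity to early
survival and growth:

1. **Amplicon genotyping** — MHC class I exon 3 (222–225 bp) 454-style
   reads are demultiplexed by exact tag + primer match and pushed through
   a five-step artifact-filter cascade: merge identical sequences; delete
   cells with < 3 reads; drop samples under the coverage threshold from
   the *genotyping score* (the probability that all `m` equally amplified
   alleles receive ≥ `t` of `T` multinomial reads — for `m = 8`, `t = 3`
   and 99.9% confidence the threshold is 104 reads); delete variants
   under 2% within a sample; require every variant in ≥ 2 independent
   PCRs; enforce length/codon phase; remove chimeras and 1-bp artifacts
   by an automated rarest-first ratio rule.
2. **Functional alleles (FA)** — DNA alleles are translated, collapsed by
   identical amino-acid sequence, and further collapsed by identity of
   the 16 peptide-binding-region (PBR) residues, encoded with the five
   physicochemical z-descriptors per residue. FAs above 10% carrier
   frequency enter the analysis as presence/absence predictors.
3. **Parental similarity** — proportion of FAs shared
   (`100/(n_m + n_f) × n_shared`), plus unweighted UniFrac distances of
   the parents' allele sets on allele- and FA-level trees (Newick input),
   and multilocus microsatellite heterozygosity.
4. **Model selection** — survival (days 1/6/12) and growth (mass/tarsus,
   days 6/12) are analysed with an all-subsets AICc rotation: pools of
   ≤ 10 variables, Akaike weights, relative variable importance
   (RVI = summed weight of models containing a variable), keep RVI > 0.5,
   refill, iterate; the final pool is model-averaged in full with
   adjusted (unconditional) SEs, and RVI > 0.7 is flagged relevant.
   Binary responses are aggregated to clutch means (weighted by clutch
   size) — the route taken when per-individual logistic mixed models do
   not converge.

A first-class synthetic-data generator emulates the study (14 aviaries,
4–5 pairs each, ~290 embryos, an engineered 85 DNA → 78 AA → 59 FA
allele pool, planted survival/growth effects, noisy tagged reads with
technical replicates), so the whole pipeline is testable end to end
without the original data. See `docs/methods.md` for the model details
and design choices.

## Worked example

The numbered drivers under `analysis/` run the full path on a synthetic
study population (seed 1):

```bash
python analysis/01_simulate.py 1        # population + reads -> results/fixtures
python analysis/02_genotype.py          # filter cascade -> results/genotypes.tsv
python analysis/03_functional_alleles.py
python analysis/04_similarity.py
python analysis/05_model_selection.py   # Tables-style output
```

`02_genotype.py` prints, for each run, the cascade's effect and the
calling accuracy against the simulator's truth:

```
run R1: 12382 variants in -> 82 out; coverage threshold 104; 3 samples failed
run R2: 12437 variants in -> 79 out; coverage threshold 104; 1 samples failed
425 individuals called; allele sensitivity 0.9981, false-allele rate 0.0000
```

— ~12,400 raw sequence variants per run collapse to ~80 true alleles;
samples below 104 reads are not called; 99.8% of true alleles are
recovered with no false calls. `03_functional_alleles.py` reports the
engineered collapse (`85 DNA alleles -> 78 AA alleles -> 59 FAs`), and
`05_model_selection.py` prints the risk-set bookkeeping
(`36/302 unhatched; 53/266 dead before day 6 (9 excluded non-natural);
31/213 dead before day 12`) and one table per response, shaped like the
study's results:

```
== survival_day6 (109 clutches, 3 rounds) ==
       variable estimate adjusted_se      p marker    rvi  relevant
    (Intercept)   0.4114      0.2985 0.1681                   False
        FA25259  -0.2636      0.0985 0.0074     ** 0.9713      True
allele_distance   0.5446      0.3642 0.1348        0.8234      True

== tarsus_day12 (182 chicks, 2 rounds) ==
    variable estimate adjusted_se      p marker    rvi  relevant
 (Intercept)  18.8824      0.1645 0.0000    ***            False
     FA00011   0.1784      0.2274 0.4328        0.5398     False
     FA00055   0.4120      0.2614 0.1150        0.8440      True
     FA18621   0.8951      0.1709 0.0000    *** 1.0000      True
clutch_order  -0.4846      0.0842 0.0000    *** 1.0000      True
```

The generator plants a −1.0 logit day-6 survival effect for carriers of
FA25259 and a +0.68 mm day-12 tarsus effect for FA18621; both surface
with RVI > 0.97 (the clutch-level survival estimate −0.26 is on the
survival-proportion scale). Day-6 mass and tarsus similarly recover the
planted FA25259 deficits (−1.34 g and −0.85 mm against planted −1.57 g
and −0.67 mm). Detection of the survival effect is probabilistic at
study size — the acceptance suite measures the detection rate across 50
replicate populations rather than asserting any single run.

The same stages are exposed as a CLI
(`sparrowmhc simulate|genotype|fa|similarity|select|run|validate`);
`sparrowmhc run` executes everything into one output directory.

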