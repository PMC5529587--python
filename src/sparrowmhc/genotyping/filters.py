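"""The artifact-filtering cascade applied to one run's count matrix.

Order follows the study protocol: merge identical sequences, delete
low-abundance cells (< 3 reads), drop samples below the coverage threshold
derived from the genotyping score, delete within-sample frequencies below
2%, require every variant in at least two independent PCRs, enforce the
expected amplicon length (222-225 bp) and codon-phase of indels, then
remove chimeras and 1-bp substitution artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .matrix import RunMatrix


@dataclass
class FilterStep:
    name: str
    variants_in: int
    variants_out: int
    reads_in: int
    reads_out: int


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, before: RunMatrix, after: RunMatrix) -> None:
        self.steps.append(FilterStep(
            name=name,
            variants_in=before.n_variants, variants_out=after.n_variants,
            reads_in=before.total_reads, reads_out=after.total_reads,
        ))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def is_monotone(self) -> bool:
        f = self.to_frame()
        return bool((f["variants_out"] <= f["variants_in"]).all()
                    and (f["reads_out"] <= f["reads_in"]).all())


def filter_low_abundance(matrix: RunMatrix, min_reads: int = 3) -> RunMatrix:
    """Zero every sample/variant cell with fewer than ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    out = matrix.copy()
    out.counts = out.counts.where(out.counts >= min_reads, 0)
    return out.drop_empty_variants()


def filter_sample_coverage(matrix: RunMatrix, threshold: int) -> tuple[RunMatrix, list[str]]:
    """Drop samples whose total retained reads fall below ``threshold``.

    Returns the filtered matrix and the list of failed samples (no genotype
    can be called for them at the requested confidence).
    """
    totals = matrix.counts.sum(axis=1)
    failed = sorted(totals.index[totals < threshold])
    out = matrix.copy()
    out.counts = out.counts.drop(index=failed)
    kept = set(out.counts.index)
    out.replicate_links = [(a, b) for a, b in out.replicate_links
                           if a in kept and b in kept]
    return out.drop_empty_variants(), failed


def filter_within_sample_frequency(matrix: RunMatrix, min_frac: float = 0.02) -> RunMatrix:
    """Zero cells below ``min_frac`` of their sample's total.

    Single pass: per-sample totals are those entering this step, not
    recomputed as cells are removed, so the outcome is independent of the
    order in which cells are visited.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must be in [0, 1]")
    out = matrix.copy()
    totals = out.counts.sum(axis=1)
    frac = out.counts.div(totals.where(totals > 0, 1), axis=0)
    out.counts = out.counts.where(frac >= min_frac, 0)
    return out.drop_empty_variants()


def filter_min_occurrence(matrix: RunMatrix, min_samples: int = 2) -> RunMatrix:
    """Drop variants seen in fewer than ``min_samples`` samples run-wide.

    Technical replicates are independent PCRs, so a variant seen in a
    sample and its replicate counts as two occurrences.
    """
    presence = (matrix.counts > 0).sum(axis=0)
    drop = presence.index[presence < min_samples]
    out = matrix.copy()
    out.counts = out.counts.drop(columns=drop)
    out.sequences = {v: s for v, s in out.sequences.items() if v not in set(drop)}
    return out


def filter_length_and_frame(matrix: RunMatrix,
                            min_len: int = 222, max_len: int = 225,
                            reference_len: int = 222,
                            enforce_frame: bool = True) -> RunMatrix:
    """Drop variants outside the expected amplicon length range, and those
    whose length difference from the reference is not a whole number of
    codons (indels that shift the reading frame are artifacts)."""
    out = matrix.copy()
    drop = []
    for vid, seq in matrix.sequences.items():
        n = len(seq)
        if n < min_len or n > max_len:
            drop.append(vid)
        elif enforce_frame and (n - reference_len) % 3 != 0:
            drop.append(vid)
    out.counts = out.counts.drop(columns=drop)
    out.sequences = {v: s for v, s in out.sequences.items() if v not in set(drop)}
    return out.drop_empty_variants()
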