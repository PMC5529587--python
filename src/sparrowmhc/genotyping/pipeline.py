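"""Genotype calling: the full per-run filter cascade plus replicate and
cross-run reconciliation into per-individual MHC allele sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .artifacts import remove_artifacts
from .filters import (
    FilterReport,
    filter_length_and_frame,
    filter_low_abundance,
    filter_min_occurrence,
    filter_sample_coverage,
    filter_within_sample_frequency,
)
from .matrix import RunMatrix, merge_identical
from .score import GenotypingScoreParams, min_reads_for_score

PASSED = "passed"
FAILED_COVERAGE = "failed_coverage"


@dataclass
class GenotypeCall:
    sample: str
    accepted: set[str]            # accepted variant/allele sequence keys
    total_reads: int
    status: str = PASSED

    def __post_init__(self) -> None:
        if self.status == FAILED_COVERAGE and self.accepted:
            raise ValueError("failed_coverage calls must have empty allele sets")


@dataclass
class RunCallResult:
    run_id: str
    calls: dict[str, GenotypeCall]
    report: FilterReport
    artifact_flags: dict = field(default_factory=dict)
    coverage_threshold: int = 0


def call_genotypes(matrix: RunMatrix,
                   params: GenotypingScoreParams | None = None,
                   *,
                   min_reads: int = 3,
                   min_frac: float = 0.02,
                   min_occurrence: int = 2,
                   min_len: int = 222, max_len: int = 225,
                   reference_len: int = 222,
                   artifact_ratio: float = 10.0,
                   coverage_threshold: int | None = None,
                   max_alleles_warn: int | None = None) -> RunCallResult:
    """Apply the five-step cascade to one run and call per-sample genotypes.

    Steps, in protocol order: merge identical sequences; delete cells with
    fewer than ``min_reads`` reads; drop samples under the coverage
    threshold (computed from the genotyping-score model unless supplied);
    delete within-sample frequencies below ``min_frac``; require each
    variant in at least ``min_occurrence`` independent PCRs; enforce
    length/codon-phase; remove chimeras and 1-bp artifacts.

    Accepted allele sets are keyed by DNA sequence (stable across runs).
    """
    params = params or GenotypingScoreParams()
    if max_alleles_warn is None:
        max_alleles_warn = params.m
    if coverage_threshold is None:
        coverage_threshold = min_reads_for_score(params)

    report = FilterReport()
    raw_totals = matrix.counts.sum(axis=1)

    m0 = merge_identical(matrix)
    report.add("merge_identical", matrix, m0)
    m1 = filter_low_abundance(m0, min_reads=min_reads)
    report.add("low_abundance", m0, m1)
    m2, failed = filter_sample_coverage(m1, coverage_threshold)
    report.add("sample_coverage", m1, m2)
    m3 = filter_within_sample_frequency(m2, min_frac=min_frac)
    report.add("within_sample_frequency", m2, m3)
    m4 = filter_min_occurrence(m3, min_samples=min_occurrence)
    report.add("min_occurrence", m3, m4)
    m5 = filter_length_and_frame(m4, min_len=min_len, max_len=max_len,
                                 reference_len=reference_len)
    report.add("length_and_frame", m4, m5)
    m6, flags = remove_artifacts(m5, ratio=artifact_ratio)
    report.add("artifacts", m5, m6)

    calls: dict[str, GenotypeCall] = {}
    for sample in matrix.counts.index:
        if sample in failed:
            calls[sample] = GenotypeCall(sample, set(), int(raw_totals[sample]),
                                         status=FAILED_COVERAGE)
            continue
        if sample not in m6.counts.index:
            calls[sample] = GenotypeCall(sample, set(), int(raw_totals[sample]))
            continue
        row = m6.counts.loc[sample]
        accepted = {m6.sequences[v] for v in row.index[row > 0]}
        calls[sample] = GenotypeCall(sample, accepted, int(raw_totals[sample]))
    return RunCallResult(run_id=matrix.run_id, calls=calls, report=report,
                         artifact_flags=flags, coverage_threshold=coverage_threshold)


def reconcile_individuals(results: list[RunCallResult],
                          sample_to_individual: dict[str, str],
                          mode: str = "union") -> dict[str, set[str]]:
    """Merge per-sample calls into per-individual allele sets.

    Replicates of one individual (and its samples across runs) are
    reconciled by union by default: the two-PCR occurrence filter has
    already demanded independent support for every retained variant.  An
    intersection mode is available for sensitivity analysis; samples that
    failed coverage do not contribute (and do not empty an intersection).
    """
    if mode not in {"union", "intersection"}:
        raise ValueError("mode must be 'union' or 'intersection'")
    merged: dict[str, set[str] | None] = {}
    for res in results:
        for sample, call in res.calls.items():
            ind = sample_to_individual.get(sample, sample)
            if call.status == FAILED_COVERAGE:
                merged.setdefault(ind, None)
                continue
            cur = merged.get(ind)
            if cur is None:
                merged[ind] = set(call.accepted)
            elif mode == "union":
                merged[ind] = cur | call.accepted
            else:
                merged[ind] = cur & call.accepted
    return {ind: (s if s is not None else set()) for ind, s in merged.items()}


def genotypes_to_frame(genotypes: dict[str, set[str]],
                       seq_to_name: dict[str, str] | None = None) -> pd.DataFrame:
    """Long-format table (individual, allele) for TSV export."""
    rows = []
    for ind in sorted(genotypes):
        for seq in sorted(genotypes[ind]):
            rows.append({"individual": ind,
                         "allele": seq_to_name.get(seq, seq) if seq_to_name else seq})
    return pd.DataFrame(rows, columns=["individual", "allele"])
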