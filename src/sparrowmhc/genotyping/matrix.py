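"""Sample-by-variant read count matrices for one sequencing run.

The genotyping substrate is a non-negative integer matrix of read counts,
one row per tagged sample (individuals and their technical replicates), one
column per unique post-trim sequence variant.  Runs are kept separate and
filtered separately; genotypes are merged per individual afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO


@dataclass
class TagMap:
    """Maps sequence tags to samples within a run.

    table columns: tag, sample, run, replicate_of (empty when the sample is
    the primary PCR of its individual).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"tag", "sample", "run", "replicate_of"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"tag map missing columns: {sorted(missing)}")
        if self.table["tag"].duplicated().any():
            dups = self.table.loc[self.table["tag"].duplicated(), "tag"].tolist()
            raise ValueError(f"duplicate tags in tag map: {dups}")

    def for_run(self, run_id: str) -> pd.DataFrame:
        return self.table[self.table["run"] == str(run_id)]

    @classmethod
    def read_tsv(cls, path) -> "TagMap":
        tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(tab)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class RunMatrix:
    """Read counts for one run: samples x variants, plus variant sequences."""

    run_id: str
    counts: pd.DataFrame                      # index samples, columns variant ids
    sequences: dict[str, str]                 # variant id -> DNA sequence
    replicate_links: list[tuple[str, str]] = field(default_factory=list)
    dropped_reads: int = 0                    # reads without complete tag+primers

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be non-negative")
        samples = set(self.counts.index)
        for a, b in self.replicate_links:
            if a not in samples or b not in samples:
                raise ValueError(f"replicate link ({a}, {b}) references unknown sample")

    @property
    def total_reads(self) -> int:
        return int(self.counts.values.sum())

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "RunMatrix":
        return RunMatrix(
            run_id=self.run_id,
            counts=self.counts.copy(),
            sequences=dict(self.sequences),
            replicate_links=list(self.replicate_links),
            dropped_reads=self.dropped_reads,
        )

    def drop_empty_variants(self) -> "RunMatrix":
        """Remove all-zero variant columns (in place) and return self."""
        keep = self.counts.columns[(self.counts != 0).any(axis=0)]
        self.counts = self.counts[keep]
        self.sequences = {v: s for v, s in self.sequences.items() if v in set(keep)}
        return self

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, sequences: dict[str, str], run_id: str = "run",
                 replicate_links: list[tuple[str, str]] | None = None) -> "RunMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(run_id=run_id, counts=counts.astype(int), sequences=sequences,
                   replicate_links=replicate_links or [])


def _variant_ids(sequences: list[str]) -> dict[str, str]:
    """Assign deterministic ids var00001... ordered by sequence string."""
    return {seq: f"var{i + 1:05d}" for i, seq in enumerate(sorted(sequences))}


def demultiplex(reads_fasta, tag_map: TagMap, run_id: str,
                fwd_primer: str, rev_primer: str) -> RunMatrix:
    """Assign reads to samples by exact tag match and strip tag + primers.

    A read is retained only if it starts with ``tag + fwd_primer`` for a tag
    registered for this run and ends with the reverse complement of
    ``rev_primer`` (exact matches; the study demanded complete tags and
    primers).  Everything between the primers is the sequence variant.
    Reads failing any condition are dropped and counted.
    """
    from Bio.Seq import Seq

    run_tags = tag_map.for_run(run_id)
    if run_tags.empty:
        raise ValueError(f"no tags registered for run {run_id!r}")
    tag_to_sample = dict(zip(run_tags["tag"], run_tags["sample"]))
    tag_lengths = sorted({len(t) for t in tag_to_sample}, reverse=True)
    fwd = fwd_primer.upper()
    rev_rc = str(Seq(rev_primer.upper()).reverse_complement())

    per_sample: dict[str, dict[str, int]] = {s: {} for s in tag_to_sample.values()}
    dropped = 0
    for rec in SeqIO.parse(str(reads_fasta), "fasta"):
        seq = str(rec.seq).upper()
        sample = None
        for tl in tag_lengths:
            candidate = tag_to_sample.get(seq[:tl])
            if candidate is not None:
                sample, tag_len = candidate, tl
                break
        if sample is None:
            dropped += 1
            continue
        body = seq[tag_len:]
        if not body.startswith(fwd) or not body.endswith(rev_rc):
            dropped += 1
            continue
        insert = body[len(fwd):len(body) - len(rev_rc)]
        if not insert:
            dropped += 1
            continue
        per_sample[sample][insert] = per_sample[sample].get(insert, 0) + 1

    all_seqs = sorted({s for cc in per_sample.values() for s in cc})
    ids = _variant_ids(all_seqs)
    counts = pd.DataFrame(0, index=sorted(per_sample), columns=[ids[s] for s in all_seqs],
                          dtype=int)
    for sample, cc in per_sample.items():
        for seq, n in cc.items():
            counts.loc[sample, ids[seq]] = n

    links = [
        (row["replicate_of"], row["sample"])
        for _, row in run_tags.iterrows()
        if row["replicate_of"]
    ]
    return RunMatrix(run_id=run_id, counts=counts,
                     sequences={v: s for s, v in ids.items()},
                     replicate_links=links, dropped_reads=dropped)


def merge_identical(matrix: RunMatrix) -> RunMatrix:
    """Merge variants with identical post-trim sequences.

    Within each sample the counts of identical sequences are summed and the
    run-wide variant set is deduplicated.  Idempotent.
    """
    seq_of_col = [matrix.sequences[v] for v in matrix.counts.columns]
    ids = _variant_ids(sorted(set(seq_of_col)))
    merged = matrix.counts.T.groupby([ids[s] for s in seq_of_col]).sum().T
    merged = merged[sorted(merged.columns)]
    return RunMatrix(run_id=matrix.run_id, counts=merged,
                     sequences={v: s for s, v in ids.items()},
                     replicate_links=list(matrix.replicate_links),
                     dropped_reads=matrix.dropped_reads)
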